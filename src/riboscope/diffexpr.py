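"""Binned z-score differential expression between two sample groups.

Transcripts are ranked by the geometric mean of their counts in the two
conditions, partitioned into consecutive bins of fixed size (default 300), and
each transcript's log2 fold change is standardized against its bin's mean and
standard deviation.  Because fold-change variance shrinks as counts grow, the
binning provides an intensity-dependent null: a transcript is called up or
down when its within-bin z-score passes the chosen threshold.  This is a
replicate-free screen, not a dispersion-modelling test.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .countstore import FIVE_PRIME, EndCountStore, merge_stores
from .metagene import OffsetTable, apply_offsets
from .reference import Reference

DEFAULT_BIN_SIZE = 300
MIN_PARTIAL_BIN = 30


def transcript_counts(
    stores: Sequence[EndCountStore] | EndCountStore,
    reference: Reference,
    region: str = "all",
    offsets: OffsetTable | None = None,
    *,
    ambiguity: str = "unambiguous",
) -> dict[str, int]:
    """Reads mapped per transcript.

    ``region="all"`` sums every 5′-end count on the transcript;
    ``region="cds"`` sums offset-adjusted A-sites falling within the annotated
    CDS (start codon through stop codon) and requires ``offsets``.
    """
    if isinstance(stores, EndCountStore):
        stores = [stores]
    merged = merge_stores(stores) if len(stores) > 1 else stores[0]
    counts: dict[str, int] = {tid: 0 for tid in reference}
    if region == "all":
        for (tid, _, end, amb, _), c in merged.counts.items():
            if end != FIVE_PRIME or tid not in counts:
                continue
            if ambiguity != "both" and amb != ambiguity:
                continue
            counts[tid] += c
    elif region == "cds":
        if offsets is None:
            raise ValueError("region='cds' requires an offset table")
        for tid in reference.coding_ids():
            rec = reference[tid]
            vec, _ = apply_offsets(
                merged, offsets, tid, rec.length, FIVE_PRIME, ambiguity=ambiguity
            )
            counts[tid] = int(vec[rec.cds_start - 1 : rec.cds_stop + 2].sum())
    else:
        raise ValueError("region must be 'all' or 'cds'")
    return counts


def zscore_differential(
    counts_a: Mapping[str, float],
    counts_b: Mapping[str, float],
    bin_size: int = DEFAULT_BIN_SIZE,
    z_threshold: float = 2.0,
    min_count: float = 1,
    normalize_totals: bool = True,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Geometric-mean binned z-score table for two count maps.

    Transcripts with a raw count below ``min_count`` in either condition are
    excluded (zeros would give infinite ratios).  With ``normalize_totals``
    each condition is scaled to counts-per-million of its own total before
    ratios are formed.  Transcripts are sorted by descending geometric mean
    ``sqrt(a * b)`` (ties broken by transcript id), cut into consecutive bins
    of ``bin_size``; a final partial bin with fewer than 30 transcripts is
    merged into the preceding bin.  Within each bin
    ``z = (log2(b/a) - mean) / sd`` with the unbiased sd; calls are ``up`` for
    ``z >= z_threshold``, ``down`` for ``z <= -z_threshold``, else ``ns``.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("count maps must cover the same transcripts")
    ids = [t for t in counts_a if counts_a[t] >= min_count and counts_b[t] >= min_count]
    if len(ids) < 2:
        raise ValueError(
            f"only {len(ids)} transcripts pass min_count={min_count}; need >= 2"
        )
    a = np.array([counts_a[t] for t in ids], dtype=float)
    b = np.array([counts_b[t] for t in ids], dtype=float)
    if normalize_totals:
        total_a = sum(counts_a.values())
        total_b = sum(counts_b.values())
        a = a * 1e6 / total_a
        b = b * 1e6 / total_b
    a = a + pseudocount
    b = b + pseudocount

    df = pd.DataFrame(
        {
            "transcript_id": ids,
            "count_a": a,
            "count_b": b,
            "geometric_mean": np.sqrt(a * b),
            "log_ratio": np.log2(b / a),
        }
    )
    df = df.sort_values(
        ["geometric_mean", "transcript_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)

    n = len(df)
    bins = np.arange(n) // bin_size
    remainder = n % bin_size
    if n > bin_size and 0 < remainder < MIN_PARTIAL_BIN:
        bins[bins == bins[-1]] = bins[-1] - 1  # fold tiny tail into last full bin
    df["bin_index"] = bins

    z = np.empty(n)
    for _, idx in df.groupby("bin_index").groups.items():
        lr = df.loc[idx, "log_ratio"]
        sd = lr.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(
                "bin with zero log-ratio variance; z-scores set to 0",
                stacklevel=2,
            )
            z[idx] = 0.0
        else:
            z[idx] = (lr - lr.mean()) / sd
    df["z_score"] = z
    df["call"] = np.select(
        [df.z_score >= z_threshold, df.z_score <= -z_threshold],
        ["up", "down"],
        default="ns",
    )
    return df.set_index("transcript_id")
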