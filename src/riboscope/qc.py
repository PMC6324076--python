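"""Dataset characterization: read-length distribution and triplet periodicity.

Ribosomes advance one codon at a time, so footprint positions inside coding
regions are 3-nt periodic.  Splitting each read length's CDS-mapped counts by
phase relative to the annotated reading frame (three bars per length) shows
how strongly a dataset is phased — the main quality signal for detecting
translated frames.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .countstore import FIVE_PRIME, EndCountStore
from .metagene import OffsetTable
from .reference import Reference


def readlength_distribution(store: EndCountStore) -> dict[int, int]:
    """Total read count per read length (marginal of 5′-end records)."""
    out: dict[int, int] = {}
    for (_, length, end, _, _), c in store.counts.items():
        if end == FIVE_PRIME:
            out[length] = out.get(length, 0) + c
    return dict(sorted(out.items()))


def triplet_periodicity(
    store: EndCountStore,
    reference: Reference,
    offsets: OffsetTable,
    *,
    use_offsets: bool = True,
) -> pd.DataFrame:
    """Per-readlength counts by phase relative to the CDS frame.

    Only unambiguous counts whose (offset-adjusted) position falls within an
    annotated coding region — start codon up to but excluding the stop codon —
    are used.  Phase 0 means in-frame with the annotated CDS.  Set
    ``use_offsets=False`` to phase raw 5′ ends instead of inferred A-sites.

    Returns a DataFrame indexed by read_length with columns f0, f1, f2 and
    in_frame_fraction (max phase count over the total).
    """
    cds = {
        tid: (reference[tid].cds_start, reference[tid].cds_stop)
        for tid in reference.coding_ids()
    }
    rows: dict[int, list[int]] = {}
    for (tid, length, end, amb, pos), c in store.counts.items():
        if end != FIVE_PRIME or amb != "unambiguous" or tid not in cds:
            continue
        start, stop = cds[tid]
        site = pos + offsets.offset_5(length) if use_offsets else pos
        if start <= site <= stop - 1:
            phase = (site - start) % 3
            rows.setdefault(length, [0, 0, 0])[phase] += c
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["f0", "f1", "f2"]
    ).sort_index()
    df.index.name = "read_length"
    totals = df.sum(axis=1)
    df["in_frame_fraction"] = df[["f0", "f1", "f2"]].max(axis=1).where(totals > 0, 0) / totals.replace(0, 1)
    return df


def distribution_to_tsv(dist: dict[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(dist.items()), columns=["read_length", "count"]
    ).to_csv(path, sep="\t", index=False)
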