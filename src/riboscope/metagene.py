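"""Metagene profiles and per-readlength A-site offset inference.

Aggregating read-end counts from all coding transcripts around annotated start
codons yields a metagene profile per read length.  Initiating ribosomes pause
with the start codon in their P-site, so the 5′ ends of their footprints pile
up at a fixed distance upstream of the start; that peak distance, plus the
3 nt separating the P- and A-sites, is the 5′-end A-site offset.  The 3′ rule
is symmetric: peak distance downstream of the start, minus 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .countstore import FIVE_PRIME, THREE_PRIME, EndCountStore
from .reference import Reference

START_CODON_ANCHOR = "start_codon"
STOP_CODON_ANCHOR = "stop_codon"

#: nt between the P-site (peak position at initiation) and the A-site
P_TO_A_SHIFT = 3

DEFAULT_WINDOW = 100
DEFAULT_FALLBACK_OFFSET = 15


@dataclass
class MetageneProfile:
    """Per-readlength count arrays over relative positions [-window, +window].

    Index ``window`` of each array is relative position 0, the first
    nucleotide of the anchor codon.
    """

    anchor: str
    end: str
    window: int
    counts: dict[int, np.ndarray] = field(default_factory=dict)

    def array(self, read_length: int) -> np.ndarray:
        empty = np.zeros(2 * self.window + 1, dtype=np.int64)
        return self.counts.get(read_length, empty)

    def combined(self) -> np.ndarray:
        """Sum over read lengths."""
        total = np.zeros(2 * self.window + 1, dtype=np.int64)
        for arr in self.counts.values():
            total += arr
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rel, length, int(arr[rel + self.window]))
            for length, arr in sorted(self.counts.items())
            for rel in range(-self.window, self.window + 1)
        ]
        return pd.DataFrame(rows, columns=["relative_position", "read_length", "count"])


@dataclass
class Offset:
    offset_5: int
    offset_3: int
    source: str = "inferred"  # or "fallback"


@dataclass
class OffsetTable:
    """Per-readlength distances mapping read ends to ribosomal A-sites.

    ``offset_5`` is added to a 5′-end position, ``offset_3`` subtracted from a
    3′-end position.  Lengths absent from the table resolve to ``fallback``.
    """

    offsets: dict[int, Offset] = field(default_factory=dict)
    fallback: int = DEFAULT_FALLBACK_OFFSET

    def offset_5(self, read_length: int) -> int:
        off = self.offsets.get(read_length)
        return off.offset_5 if off is not None else self.fallback

    def offset_3(self, read_length: int) -> int:
        off = self.offsets.get(read_length)
        return off.offset_3 if off is not None else self.fallback

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (length, o.offset_5, o.offset_3, o.source)
            for length, o in sorted(self.offsets.items())
        ]
        pd.DataFrame(
            rows, columns=["read_length", "offset_5", "offset_3", "source"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, fallback: int = DEFAULT_FALLBACK_OFFSET) -> "OffsetTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(fallback=fallback)
        for row in df.itertuples(index=False):
            table.offsets[int(row.read_length)] = Offset(
                int(row.offset_5), int(row.offset_3), str(row.source)
            )
        return table


def metagene_profile(
    store: EndCountStore,
    reference: Reference,
    anchor: str = START_CODON_ANCHOR,
    end: str = FIVE_PRIME,
    window: int = DEFAULT_WINDOW,
    ambiguity: str = "unambiguous",
) -> MetageneProfile:
    """Aggregate read-end counts around start (or stop) codons.

    Uses every coding transcript with at least ``window`` nt on both sides of
    the anchor so each transcript can contribute to the full window.
    """
    coding = reference.coding_ids()
    if not coding:
        raise ValueError("reference contains no coding transcripts")
    anchors: dict[str, int] = {}
    for tid in coding:
        rec = reference[tid]
        pos = rec.cds_start if anchor == START_CODON_ANCHOR else rec.cds_stop
        if pos - 1 >= window and rec.length - pos >= window:
            anchors[tid] = pos
    profile = MetageneProfile(anchor=anchor, end=end, window=window)
    for (tid, length, e, amb, pos), c in store.counts.items():
        if e != end or tid not in anchors:
            continue
        if ambiguity != "both" and amb != ambiguity:
            continue
        rel = pos - anchors[tid]
        if -window <= rel <= window:
            arr = profile.counts.get(length)
            if arr is None:
                arr = profile.counts[length] = np.zeros(
                    2 * window + 1, dtype=np.int64
                )
            arr[rel + window] += c
    return profile


def _peak(arr: np.ndarray, window: int, rels: range) -> int | None:
    """Relative position of the maximum of ``arr`` over ``rels``; ties break
    toward the smallest absolute distance; None when the range is all zero."""
    best_rel, best = None, 0
    for rel in sorted(rels, key=abs):
        v = int(arr[rel + window])
        if v > best:
            best, best_rel = v, rel
    return best_rel


def infer_offsets(
    mg5: MetageneProfile,
    mg3: MetageneProfile,
    fallback: int = DEFAULT_FALLBACK_OFFSET,
) -> OffsetTable:
    """Infer per-readlength A-site offsets from start-anchored metagenes.

    5′ rule: distance from the highest peak upstream of the start codon to the
    start codon, plus 3.  3′ rule: distance to the highest peak downstream,
    minus 3.  Read lengths with no signal in the search range get the fallback
    offset and a warning.
    """
    if mg5.end != FIVE_PRIME or mg3.end != THREE_PRIME:
        raise ValueError("expected a five_prime and a three_prime metagene profile")
    table = OffsetTable(fallback=fallback)
    lengths = sorted(set(mg5.counts) | set(mg3.counts))
    for length in lengths:
        w5, w3 = mg5.window, mg3.window
        arr5 = np.asarray(mg5.array(length))
        arr3 = np.asarray(mg3.array(length))
        peak5 = _peak(arr5, w5, range(-w5, 0))
        peak3 = _peak(arr3, w3, range(1, w3 + 1))
        source = "inferred"
        if peak5 is None:
            off5, source = fallback, "fallback"
        else:
            off5 = abs(peak5) + P_TO_A_SHIFT
        if peak3 is None:
            off3, source = fallback, "fallback"
        else:
            off3 = peak3 - P_TO_A_SHIFT
        if not (0 < off5 <= length):
            off5, source = fallback, "fallback"
        if not (0 < off3 <= length):
            off3, source = fallback, "fallback"
        if source == "fallback":
            warnings.warn(
                f"read length {length}: no usable metagene peak; "
                f"using fallback offset {fallback}",
                stacklevel=2,
            )
        table.offsets[length] = Offset(off5, off3, source)
    return table


def apply_offsets(
    store: EndCountStore,
    offsets: OffsetTable,
    transcript_id: str,
    transcript_length: int,
    end_choice: str = FIVE_PRIME,
    *,
    min_length: int | None = None,
    max_length: int | None = None,
    ambiguity: str = "unambiguous",
    site: str = "a",
) -> tuple[np.ndarray, int]:
    """Offset-adjust one transcript's end counts to a per-position site vector.

    Returns ``(vector, dropped)`` where ``vector[i]`` is the count whose
    inferred site is transcript position ``i + 1`` and ``dropped`` tallies
    counts pushed outside [1, length].  ``site="p"`` reports P-site positions
    (3 nt upstream of the A-site).
    """
    if site not in ("a", "p"):
        raise ValueError("site must be 'a' or 'p'")
    shift = 0 if site == "a" else -P_TO_A_SHIFT
    vec = np.zeros(transcript_length, dtype=np.int64)
    dropped = 0
    for (length, pos), c in store.position_counts(
        transcript_id,
        end_choice,
        min_length=min_length,
        max_length=max_length,
        ambiguity=ambiguity,
    ).items():
        if end_choice == FIVE_PRIME:
            target = pos + offsets.offset_5(length) + shift
        else:
            target = pos - offsets.offset_3(length) + shift
        if 1 <= target <= transcript_length:
            vec[target - 1] += c
        else:
            dropped += c
    return vec, dropped
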