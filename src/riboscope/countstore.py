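"""Per-transcript, per-readlength read-end count store.

Each retained alignment contributes one count at its 5′-end position and one
at its 3′-end position, keyed by (transcript, read length, end, ambiguity,
position).  This is the central quantification object: metagenes, offsets, QC
and profiles are all marginals of it.  Stores persist as a single-file SQLite
database (tables ``counts`` and ``meta``) so any language can read them.
"""

from __future__ import annotations

import sqlite3
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .reference import Reference

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"

STORE_FORMAT_VERSION = "1"
DEFAULT_MIN_LENGTH = 25

#: (transcript_id, read_length, end, ambiguity, position)
RecordKey = tuple[str, int, str, str, int]


class StoreError(Exception):
    """Raised for malformed store files or incompatible merges."""


def length_filter(read_length: int, min_length: int = DEFAULT_MIN_LENGTH) -> bool:
    """Keep a read iff its length is at least ``min_length`` nucleotides.

    Footprints shorter than the minimum are too short to be genuine
    ribosome-protected fragments and are removed up front.
    """
    if read_length < 0:
        raise ValueError("read length must be non-negative")
    return read_length >= min_length


@dataclass
class EndCountStore:
    """Indexed read-end counts plus sample metadata.

    ``counts`` maps (transcript_id, read_length, end, ambiguity, position) to
    a non-negative integer; positions are 1-based transcript coordinates.
    """

    sample_id: str = "sample"
    sequence_type: str = "riboseq"
    assembly: str = "custom"
    min_read_length: int = DEFAULT_MIN_LENGTH
    total_retained_reads: int = 0
    counts: Counter = field(default_factory=Counter)
    skipped: Counter = field(default_factory=Counter)

    def add(
        self,
        transcript_id: str,
        read_length: int,
        position: int,
        end: str,
        ambiguity: str = UNAMBIGUOUS,
        n: int = 1,
    ) -> None:
        self.counts[(transcript_id, read_length, end, ambiguity, position)] += n

    def iter_records(self) -> Iterator[tuple[RecordKey, int]]:
        return iter(self.counts.items())

    def read_lengths(self) -> list[int]:
        return sorted({k[1] for k in self.counts})

    def transcripts(self) -> list[str]:
        return sorted({k[0] for k in self.counts})

    def end_total(self, end: str) -> int:
        return sum(c for k, c in self.counts.items() if k[2] == end)

    def position_counts(
        self,
        transcript_id: str,
        end: str = FIVE_PRIME,
        *,
        min_length: int | None = None,
        max_length: int | None = None,
        ambiguity: str = UNAMBIGUOUS,
    ) -> dict[tuple[int, int], int]:
        """Counts for one transcript as {(read_length, position): count}.

        ``ambiguity`` is ``"unambiguous"``, ``"ambiguous"`` or ``"both"``.
        """
        out: Counter = Counter()
        for (tid, length, e, amb, pos), c in self.counts.items():
            if tid != transcript_id or e != end:
                continue
            if ambiguity != "both" and amb != ambiguity:
                continue
            if min_length is not None and length < min_length:
                continue
            if max_length is not None and length > max_length:
                continue
            out[(length, pos)] += c
        return dict(out)

    def summary(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "sequence_type": self.sequence_type,
            "assembly": self.assembly,
            "min_read_length": self.min_read_length,
            "total_retained_reads": self.total_retained_reads,
            "skipped": dict(self.skipped),
            "n_records": len(self.counts),
        }


def quantify_alignments(
    alignment_path: str | Path,
    reference: Reference,
    min_length: int = DEFAULT_MIN_LENGTH,
    *,
    sample_id: str | None = None,
    sequence_type: str = "riboseq",
) -> EndCountStore:
    """Reduce a transcriptome-aligned SAM/BAM to an :class:`EndCountStore`.

    Each retained alignment adds one count to its 5′-end record and one to its
    3′-end record (3′ = 5′ + length − 1, lengths from the aligned query with
    soft-clips excluded).  A read reported at more than one location — via
    secondary flags or repeated query names — contributes once per location
    under ``ambiguity="ambiguous"``.  Unmapped and reverse-strand alignments
    are discarded; alignments to transcripts absent from ``reference`` are
    tallied in the skip summary.
    """
    alignment_path = Path(alignment_path)
    if not alignment_path.exists():
        raise FileNotFoundError(str(alignment_path))
    store = EndCountStore(
        sample_id=sample_id or alignment_path.stem,
        sequence_type=sequence_type,
        assembly=reference.assembly,
        min_read_length=min_length,
    )

    mode = "rb" if alignment_path.suffix == ".bam" else "r"
    # pass 1: count mapped alignments per query name to flag multimappers
    n_align: Counter = Counter()
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if not aln.is_unmapped:
                n_align[aln.query_name] += 1

    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                store.skipped["unmapped"] += 1
                continue
            if aln.is_reverse:
                store.skipped["reverse_strand"] += 1
                continue
            read_length = aln.query_alignment_length
            if not length_filter(read_length, min_length):
                store.skipped["short"] += 1
                continue
            tid = aln.reference_name
            if tid not in reference:
                store.skipped["unknown_reference"] += 1
                continue
            pos5 = aln.reference_start + 1
            pos3 = pos5 + read_length - 1
            tlen = reference[tid].length
            if pos5 < 1 or pos3 > tlen:
                store.skipped["out_of_bounds"] += 1
                continue
            amb = AMBIGUOUS if n_align[aln.query_name] > 1 else UNAMBIGUOUS
            store.add(tid, read_length, pos5, FIVE_PRIME, amb)
            store.add(tid, read_length, pos3, THREE_PRIME, amb)
            store.total_retained_reads += 1
    return store


def merge_stores(stores: Iterable[EndCountStore]) -> EndCountStore:
    """Record-wise sum of stores built against the same assembly."""
    stores = list(stores)
    if not stores:
        raise ValueError("nothing to merge")
    assemblies = {s.assembly for s in stores}
    if len(assemblies) > 1:
        raise StoreError(f"assembly mismatch across stores: {sorted(assemblies)}")
    merged = EndCountStore(
        sample_id="+".join(s.sample_id for s in stores),
        sequence_type=stores[0].sequence_type,
        assembly=stores[0].assembly,
        min_read_length=min(s.min_read_length for s in stores),
    )
    for s in stores:
        merged.counts.update(s.counts)
        merged.skipped.update(s.skipped)
        merged.total_retained_reads += s.total_retained_reads
    return merged


def write_store(store: EndCountStore, path: str | Path) -> None:
    """Persist a store as a single-file SQLite database."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(str(path))
    try:
        con.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        con.execute(
            "CREATE TABLE counts (transcript_id TEXT, read_length INTEGER, "
            "end TEXT, ambiguity TEXT, position INTEGER, count INTEGER)"
        )
        meta = {
            "format_version": STORE_FORMAT_VERSION,
            "sample_id": store.sample_id,
            "sequence_type": store.sequence_type,
            "assembly": store.assembly,
            "min_read_length": str(store.min_read_length),
            "total_retained_reads": str(store.total_retained_reads),
        }
        con.executemany("INSERT INTO meta VALUES (?, ?)", meta.items())
        con.executemany(
            "INSERT INTO counts VALUES (?, ?, ?, ?, ?, ?)",
            ((t, l, e, a, p, c) for (t, l, e, a, p), c in store.counts.items()),
        )
        con.execute(
            "CREATE INDEX idx_counts ON counts (transcript_id, read_length, end)"
        )
        con.commit()
    finally:
        con.close()


def read_store(path: str | Path) -> EndCountStore:
    """Load a store written by :func:`write_store`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    con = sqlite3.connect(str(path))
    try:
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"{path} is not a count-store file") from exc
        version = meta.get("format_version")
        if version != STORE_FORMAT_VERSION:
            raise StoreError(
                f"store format version {version!r} != {STORE_FORMAT_VERSION!r}; "
                "re-quantify the alignments with this version of the tool"
            )
        store = EndCountStore(
            sample_id=meta["sample_id"],
            sequence_type=meta["sequence_type"],
            assembly=meta["assembly"],
            min_read_length=int(meta["min_read_length"]),
            total_retained_reads=int(meta["total_retained_reads"]),
        )
        for t, l, e, a, p, c in con.execute(
            "SELECT transcript_id, read_length, end, ambiguity, position, count FROM counts"
        ):
            store.counts[(t, int(l), e, a, int(p))] = int(c)
        return store
    finally:
        con.close()


def position_vector(
    store: EndCountStore,
    transcript_id: str,
    transcript_length: int,
    end: str = FIVE_PRIME,
    **filters,
) -> np.ndarray:
    """Dense per-position count vector (index 0 ↔ transcript position 1)."""
    vec = np.zeros(transcript_length, dtype=np.int64)
    for (_, pos), c in store.position_counts(transcript_id, end, **filters).items():
        vec[pos - 1] += c
    return vec
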