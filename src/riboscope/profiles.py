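"""Single-transcript subcodon profiles and multi-sample comparison profiles.

A transcript profile places every footprint's inferred A-site on the
transcript and splits the resulting density into the three reading frames
(position ``i`` belongs to frame ``(i - 1) % 3``), alongside the transcript's
three-frame ORF architecture.  When ribosomes translate an ORF, the A-site
density concentrates in that ORF's frame — so frame-coloured profiles reveal
which ORFs (including nested and upstream ORFs) are translated.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .countstore import (
    FIVE_PRIME,
    EndCountStore,
    StoreError,
    merge_stores,
)
from .metagene import OffsetTable, apply_offsets
from .reference import OrfArchitecture, Reference, orf_architecture

RIBOSEQ = "riboseq"
RNASEQ = "rnaseq"


@dataclass
class TranscriptProfile:
    """Offset-adjusted per-position counts split by reading frame."""

    transcript_id: str
    asite_counts: np.ndarray
    frame_series: np.ndarray  # shape (3, length)
    architecture: OrfArchitecture
    options: dict = field(default_factory=dict)
    dropped: int = 0

    def dominant_frame(self, start: int, stop: int) -> int:
        """Frame with the highest total count over positions [start, stop]."""
        totals = self.frame_series[:, start - 1 : stop].sum(axis=1)
        return int(np.argmax(totals))


@dataclass
class ProfileGroup:
    label: str
    vector: np.ndarray
    sequence_type: str
    color: str = ""
    normalized: bool = False
    scale_factor: float = 1.0


@dataclass
class ComparisonProfile:
    transcript_id: str
    groups: list[ProfileGroup]


def _resolve_transcript(reference: Reference, transcript_id: str) -> None:
    if transcript_id in reference:
        return
    hints: list[str] = []
    gene_hits = reference.transcripts_for_gene(transcript_id)
    if gene_hits:
        hints.append(f"gene {transcript_id} has transcripts: {', '.join(gene_hits)}")
    close = difflib.get_close_matches(
        transcript_id, list(reference.genes) + list(reference.records), n=3
    )
    if close:
        hints.append(f"close matches: {', '.join(close)}")
    raise KeyError(
        f"unknown transcript {transcript_id!r}" + ("; " + "; ".join(hints) if hints else "")
    )


def split_frames(asite_counts: np.ndarray) -> np.ndarray:
    """Per-frame series: frame f keeps counts at positions p with (p-1)%3==f."""
    length = asite_counts.shape[0]
    series = np.zeros((3, length), dtype=asite_counts.dtype)
    for f in range(3):
        series[f, f::3] = asite_counts[f::3]
    return series


def transcript_profile(
    stores: Sequence[EndCountStore] | EndCountStore,
    reference: Reference,
    offsets: OffsetTable,
    transcript_id: str,
    min_length: int | None = None,
    max_length: int | None = None,
    ambiguity: str = "unambiguous",
    site: str = "a",
) -> TranscriptProfile:
    """Build a frame-split A-site profile for one transcript.

    Stores are merged, read-length bounds and the ambiguity mode applied, the
    per-readlength offsets applied to 5′ ends, and the resulting density split
    by positional frame.  The ORF architecture rides along for plotting.
    """
    if isinstance(stores, EndCountStore):
        stores = [stores]
    _resolve_transcript(reference, transcript_id)
    merged = merge_stores(stores) if len(stores) > 1 else stores[0]
    if merged.assembly != reference.assembly:
        raise StoreError(
            f"store assembly {merged.assembly!r} != reference {reference.assembly!r}"
        )
    rec = reference[transcript_id]
    vec, dropped = apply_offsets(
        merged,
        offsets,
        transcript_id,
        rec.length,
        FIVE_PRIME,
        min_length=min_length,
        max_length=max_length,
        ambiguity=ambiguity,
        site=site,
    )
    return TranscriptProfile(
        transcript_id=transcript_id,
        asite_counts=vec,
        frame_series=split_frames(vec),
        architecture=orf_architecture(rec),
        options={
            "min_length": min_length,
            "max_length": max_length,
            "ambiguity": ambiguity,
            "site": site,
        },
        dropped=dropped,
    )


def _coverage_vector(
    store: EndCountStore,
    transcript_id: str,
    transcript_length: int,
    ambiguity: str = "unambiguous",
) -> np.ndarray:
    """Full-read coverage from 5′-end records: a read of length L starting at
    p covers positions p .. p+L-1."""
    vec = np.zeros(transcript_length, dtype=np.int64)
    for (length, pos), c in store.position_counts(
        transcript_id, FIVE_PRIME, ambiguity=ambiguity
    ).items():
        vec[pos - 1 : pos - 1 + length] += c
    return vec


def compare_profiles(
    groups: Sequence[tuple[str, Sequence[EndCountStore], str]],
    reference: Reference,
    offsets: OffsetTable,
    transcript_id: str,
    normalize: bool = True,
    *,
    ambiguity: str = "unambiguous",
    colors: Sequence[str] | None = None,
) -> ComparisonProfile:
    """Per-group density vectors on one transcript for visual comparison.

    Each group is ``(label, stores, sequence_type)``.  Ribo-Seq groups use
    offset-adjusted A-site densities; RNA-Seq groups use full-read coverage
    (offsets are a ribosome concept).  With ``normalize`` on, each vector is
    scaled to reads-per-million of the group's retained read total, which
    makes libraries of different depths comparable.
    """
    if not groups:
        raise ValueError("at least one group required")
    _resolve_transcript(reference, transcript_id)
    rec = reference[transcript_id]
    out: list[ProfileGroup] = []
    for i, (label, stores, seq_type) in enumerate(groups):
        if isinstance(stores, EndCountStore):
            stores = [stores]
        merged = merge_stores(stores) if len(stores) > 1 else stores[0]
        if merged.assembly != reference.assembly:
            raise StoreError(
                f"group {label!r}: store assembly {merged.assembly!r} != "
                f"reference {reference.assembly!r}"
            )
        if seq_type == RNASEQ:
            vec = _coverage_vector(merged, transcript_id, rec.length, ambiguity)
        else:
            vec, _ = apply_offsets(
                merged, offsets, transcript_id, rec.length, FIVE_PRIME,
                ambiguity=ambiguity,
            )
        vec = vec.astype(float)
        scale = 1.0
        if normalize:
            total = merged.total_retained_reads
            scale = 1e6 / total if total else 0.0
            vec = vec * scale
        out.append(
            ProfileGroup(
                label=label,
                vector=vec,
                sequence_type=seq_type,
                color=colors[i] if colors else f"C{i}",
                normalized=normalize,
                scale_factor=scale,
            )
        )
    return ComparisonProfile(transcript_id=transcript_id, groups=out)


def export_profile_csv(
    profile: TranscriptProfile, reference: Reference, path: str | Path
) -> None:
    """One row per transcript position: nucleotide, per-frame counts, total."""
    rec = reference[profile.transcript_id]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["position", "nucleotide", "count_frame0", "count_frame1",
             "count_frame2", "total"]
        )
        for i in range(rec.length):
            writer.writerow(
                [
                    i + 1,
                    rec.sequence[i],
                    int(profile.frame_series[0, i]),
                    int(profile.frame_series[1, i]),
                    int(profile.frame_series[2, i]),
                    int(profile.asite_counts[i]),
                ]
            )
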