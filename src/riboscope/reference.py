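"""Transcriptome reference: transcript records, CDS coordinates, ORF architecture.

A transcriptome FASTA supplies the sequence of each transcript; a GTF supplies
the exon layout and CDS features in genomic coordinates.  CDS coordinates are
projected through the exon structure into 1-based transcript coordinates, the
coordinate frame used by every other module.  ``cds_start`` is the first
nucleotide of the start codon and ``cds_stop`` the first nucleotide of the stop
codon, both 1-based and inclusive.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class ReferenceError(Exception):
    """Raised when FASTA/GTF inputs are inconsistent."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript's sequence and CDS annotation.

    ``cds_start``/``cds_stop`` are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_name: str
    sequence: str
    cds_start: int | None = None
    cds_stop: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_stop is not None

    def __post_init__(self) -> None:
        if self.is_coding:
            if not (1 <= self.cds_start < self.cds_stop <= self.length - 2):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_stop}] "
                    f"outside transcript of length {self.length}"
                )
            if (self.cds_stop - self.cds_start) % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: start and stop codons not in the same frame"
                )


@dataclass(frozen=True)
class OrfArchitecture:
    """Start (AUG) and stop codon positions for each of the three frames.

    Frame ``f`` holds 1-based positions ``p`` with ``(p - 1) % 3 == f``,
    each the first nucleotide of the codon.
    """

    starts: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]
    stops: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]


def orf_architecture(record: "TranscriptRecord | str") -> OrfArchitecture:
    """Exhaustive three-frame scan for AUG and stop codons.

    Accepts a :class:`TranscriptRecord` or a plain DNA string.  Codons
    containing ``N`` are neither starts nor stops.
    """
    seq = record.sequence if isinstance(record, TranscriptRecord) else record
    seq = seq.upper()
    starts: list[list[int]] = [[], [], []]
    stops: list[list[int]] = [[], [], []]
    for i in range(len(seq) - 2):
        codon = seq[i : i + 3]
        if codon == START_CODON:
            starts[i % 3].append(i + 1)
        elif codon in STOP_CODONS:
            stops[i % 3].append(i + 1)
    return OrfArchitecture(
        starts=tuple(tuple(v) for v in starts),
        stops=tuple(tuple(v) for v in stops),
    )


@dataclass
class Reference:
    """Collection of :class:`TranscriptRecord` keyed by transcript id."""

    records: dict[str, TranscriptRecord]
    assembly: str = "custom"
    genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            for tid, rec in self.records.items():
                self.genes.setdefault(rec.gene_name, []).append(tid)

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self.records[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def coding_ids(self) -> list[str]:
        return [tid for tid, r in self.records.items() if r.is_coding]

    def transcripts_for_gene(self, gene_name: str) -> list[str]:
        """All transcript ids annotated to ``gene_name`` (caller picks one)."""
        return list(self.genes.get(gene_name, []))

    def write_manifest(self, path: str | Path) -> None:
        manifest = [
            {
                "transcript_id": r.transcript_id,
                "gene_name": r.gene_name,
                "length": r.length,
                "cds_start": r.cds_start,
                "cds_stop": r.cds_stop,
            }
            for r in self.records.values()
        ]
        Path(path).write_text(json.dumps(manifest, indent=1))


def _attr(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def _project(genomic_pos: int, exons: list[tuple[int, int]], strand: str) -> int:
    """Genomic position -> 1-based transcript coordinate via the exon walk.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, sorted in
    transcription order (ascending for '+', descending for '-').
    """
    offset = 0
    for start, end in exons:
        if start <= genomic_pos <= end:
            if strand == "-":
                return offset + (end - genomic_pos) + 1
            return offset + (genomic_pos - start) + 1
        offset += end - start + 1
    raise ReferenceError(f"genomic position {genomic_pos} not covered by exons")


def build_reference(
    fasta_path: str | Path,
    gtf_path: str | Path,
    assembly: str | None = None,
) -> Reference:
    """Load a transcriptome FASTA + GTF into a :class:`Reference`.

    CDS transcript coordinates are obtained by projecting genomic CDS features
    through the transcript's exon chain.  GTFs that exclude the stop codon from
    CDS features (Gencode style) are handled via their ``stop_codon`` features,
    or, failing that, by checking whether the last CDS codon is itself a stop.
    Transcripts whose CDS span is not a whole number of codons are demoted to
    non-coding with a warning.
    """
    fasta_path = Path(fasta_path)
    gtf_path = Path(gtf_path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ReferenceError(f"no FASTA records in {fasta_path}")

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stop_feats: dict[str, list[tuple[int, int]]] = {}
    strand: dict[str, str] = {}
    gene_of: dict[str, str] = {}

    for feat in db.all_features():
        tid = _attr(feat, "transcript_id")
        if tid is None:
            continue
        strand[tid] = feat.strand
        gname = _attr(feat, "gene_name", "gene_id")
        if gname is not None:
            gene_of.setdefault(tid, gname)
        interval = (feat.start, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(interval)
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append(interval)
        elif feat.featuretype == "stop_codon":
            stop_feats.setdefault(tid, []).append(interval)

    for tid in cds:
        if tid not in seqs:
            raise ReferenceError(
                f"transcript {tid} has CDS annotation but no FASTA sequence"
            )

    records: dict[str, TranscriptRecord] = {}
    for tid, seq in seqs.items():
        gene = gene_of.get(tid, tid)
        cds_start = cds_stop = None
        if tid in cds:
            st = strand.get(tid, "+")
            tx_exons = sorted(exons.get(tid, cds[tid]), reverse=(st == "-"))
            cds_iv = cds[tid]
            if tid in stop_feats:
                cds_iv = cds_iv + stop_feats[tid]
            gpos = [p for s, e in cds_iv for p in (s, e)]
            first_nt = max(gpos) if st == "-" else min(gpos)
            last_nt = min(gpos) if st == "-" else max(gpos)
            try:
                t1 = _project(first_nt, tx_exons, st)
                t2 = _project(last_nt, tx_exons, st)
            except ReferenceError as exc:
                raise ReferenceError(f"transcript {tid}: {exc}") from exc
            span = t2 - t1 + 1
            if span % 3 != 0 or span < 6:
                warnings.warn(
                    f"transcript {tid}: CDS span of {span} nt is not a whole "
                    "number of codons; marking non-coding",
                    stacklevel=2,
                )
            elif tid in stop_feats or seq[t2 - 3 : t2] in STOP_CODONS:
                # CDS interval ends with (or stop_codon feature supplies) the stop
                cds_start, cds_stop = t1, t2 - 2
            elif t2 + 3 <= len(seq) and seq[t2 : t2 + 3] in STOP_CODONS:
                # Gencode style without stop_codon features: stop follows the CDS
                cds_start, cds_stop = t1, t2 + 1
            else:
                cds_start, cds_stop = t1, t2 - 2
                logger.debug("transcript %s: no stop codon found at CDS end", tid)
        try:
            records[tid] = TranscriptRecord(
                transcript_id=tid,
                gene_name=gene,
                sequence=seq,
                cds_start=cds_start,
                cds_stop=cds_stop,
            )
        except ValueError as exc:
            warnings.warn(f"{exc}; marking non-coding", stacklevel=2)
            records[tid] = TranscriptRecord(
                transcript_id=tid, gene_name=gene, sequence=seq
            )

    return Reference(records=records, assembly=assembly or fasta_path.stem)
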