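"""Synthetic transcriptomes and ribosome footprint alignments with known truth.

The generator emulates the data regimes the rest of the package analyses:
coding transcripts (AUG…stop CDS flanked by UTRs, optionally with a nested
ORF in a shifted frame), and footprints whose 5′ ends sit at a fixed,
per-readlength distance upstream of the ribosome's A-site.  A-sites are drawn
codon-wise over the CDS with a configurable in-frame fraction; a configurable
share of reads represents initiation-paused ribosomes (start codon in the
P-site, A-site on codon 2), which produces the metagene peak used for offset
calibration.  Every output is accompanied by its truth (reference manifest,
end-count store, A-site density, per-transcript read counts), so downstream
modules can be tested without any external data.

The random stream is partitioned per transcript: changing ``n_transcripts``
never reshuffles earlier transcripts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .countstore import FIVE_PRIME, THREE_PRIME, UNAMBIGUOUS, EndCountStore
from .reference import Reference, TranscriptRecord

NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]
STOPS = ["TAA", "TAG", "TGA"]

#: read-length distribution typical of ribosome footprints (25-35 nt, mode 30)
DEFAULT_LENGTH_DIST = {
    25: 0.02, 26: 0.03, 27: 0.05, 28: 0.10, 29: 0.15, 30: 0.20,
    31: 0.15, 32: 0.12, 33: 0.08, 34: 0.06, 35: 0.04,
}

#: canonical 5' end -> A-site distance (P-site at 12 nt, plus one codon)
DEFAULT_ASITE_OFFSET = 15


class ConfigError(ValueError):
    pass


@dataclass
class NestedOrfSpec:
    """Internal ORF in a shifted frame inside transcript ``transcript_index``'s CDS."""

    transcript_index: int = 0
    start_codon_index: int = 10  # codons into the main CDS where the nested AUG sits
    n_codons: int = 30
    density: float = 0.5  # fraction of the transcript's reads translating it


@dataclass
class SimulationConfig:
    n_transcripts: int = 20
    cds_codons: tuple[int, int] = (80, 200)  # uniform inclusive, incl. start, excl. stop
    utr5: int = 120
    utr3: int = 120
    read_lengths: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    asite_offsets: dict[int, int] | int = DEFAULT_ASITE_OFFSET
    in_frame_fraction: float = 0.9
    initiation_fraction: float = 0.1
    n_reads: int = 10_000  # expected library size
    expression_sigma: float = 0.75  # lognormal spread of per-transcript expression
    nested_orf: NestedOrfSpec | None = None
    seed: int = 0
    assembly: str = "sim"

    def asite_offset(self, read_length: int) -> int:
        if isinstance(self.asite_offsets, dict):
            return self.asite_offsets[read_length]
        return self.asite_offsets

    def validate(self) -> None:
        probs = np.array(list(self.read_lengths.values()))
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigError("read length probabilities must sum to 1")
        if not (1 / 3 <= self.in_frame_fraction <= 1):
            raise ConfigError("in_frame_fraction must lie in [1/3, 1]")
        max_len = max(self.read_lengths)
        for length in self.read_lengths:
            delta = self.asite_offset(length)
            if not (0 < delta < length):
                raise ConfigError(f"A-site distance {delta} invalid for length {length}")
        if self.utr5 < max(self.asite_offset(length) for length in self.read_lengths):
            raise ConfigError("5' UTR shorter than the largest A-site distance")
        if self.utr3 < max_len:
            raise ConfigError("3' UTR must accommodate read overhang past the CDS")


@dataclass
class SimulatedTranscriptome:
    reference: Reference
    manifest: list[dict]
    gtf_lines: list[str]

    def write(self, out_dir: str | Path) -> tuple[Path, Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "transcriptome.fa"
        gtf = out_dir / "annotation.gtf"
        truth = out_dir / "transcriptome_truth.json"
        with open(fasta, "w") as fh:
            for tid, rec in self.reference.records.items():
                fh.write(f">{tid}\n")
                for i in range(0, rec.length, 70):
                    fh.write(rec.sequence[i : i + 70] + "\n")
        gtf.write_text("".join(self.gtf_lines))
        truth.write_text(json.dumps(self.manifest, indent=1))
        return fasta, gtf, truth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _transcript_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), stream, index])


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate coding transcripts plus a GTF describing them on a toy genome.

    Transcripts rotate through three genomic layouts (single-exon forward,
    two-exon forward, single-exon reverse) so that the CDS projection through
    exon chains is exercised in every build.  GTF CDS features include the
    stop codon.
    """
    config.validate()
    records: dict[str, TranscriptRecord] = {}
    manifest: list[dict] = []
    gtf_lines: list[str] = []
    for i in range(config.n_transcripts):
        rng = _transcript_rng(config.seed, 1, i)
        tid = f"TX{i:04d}"
        gene = f"G{i:04d}"
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        body = "".join(rng.choice(NON_STOP_CODONS, size=n_codons - 1))
        cds = "ATG" + body + str(rng.choice(STOPS))
        seq = (
            _random_seq(rng, config.utr5) + cds + _random_seq(rng, config.utr3)
        )
        cds_start = config.utr5 + 1
        cds_stop = cds_start + 3 * n_codons  # first nt of the stop codon
        nested = None
        spec = config.nested_orf
        if spec is not None and spec.transcript_index == i:
            seq, nested = _insert_nested_orf(seq, cds_start, cds_stop, spec)
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_name=gene,
            sequence=seq,
            cds_start=cds_start,
            cds_stop=cds_stop,
        )
        records[tid] = rec
        chrom = f"chr_{tid}"
        layout = i % 3
        gtf_lines.extend(_gtf_features(rec, chrom, layout, gene))
        entry = {
            "transcript_id": tid,
            "gene_name": gene,
            "length": rec.length,
            "cds_start": cds_start,
            "cds_stop": cds_stop,
            "chrom": chrom,
        }
        if nested:
            entry["nested_orf"] = nested
        manifest.append(entry)
    reference = Reference(records=records, assembly=config.assembly)
    return SimulatedTranscriptome(reference, manifest, gtf_lines)


def _insert_nested_orf(
    seq: str, cds_start: int, cds_stop: int, spec: NestedOrfSpec
) -> tuple[str, dict]:
    """Overwrite an AUG…stop in frame +1 inside the CDS.

    With a +1 frame shift neither the inserted AUG nor the inserted stop can
    create a stop codon in the main frame (main-frame codons overlapping them
    end in T or start with G/A), so the main ORF stays intact.
    """
    q = cds_start + 3 * spec.start_codon_index + 1  # frame (main+1)
    qe = q + 3 * spec.n_codons  # first nt of nested stop codon
    if q < cds_start + 4 or qe + 2 > cds_stop - 1:
        raise ConfigError("nested ORF does not fit inside the CDS")
    chars = list(seq)
    chars[q - 1 : q + 2] = "ATG"
    chars[qe - 1 : qe + 2] = "TAA"
    return "".join(chars), {"start": q, "stop": qe, "frame_shift": 1}


def _gtf_features(
    rec: TranscriptRecord, chrom: str, layout: int, gene: str
) -> list[str]:
    L = rec.length
    c1, c2 = rec.cds_start, rec.cds_stop + 2  # CDS incl. stop codon
    if layout == 0:  # single exon, forward
        strand = "+"
        exons = [(101, 100 + L)]
        cds = [(100 + c1, 100 + c2)]
    elif layout == 1:  # two exons, forward, 50 nt intron
        strand = "+"
        m = L // 2
        exons = [(101, 100 + m), (151 + m, 150 + L)]
        cds = []
        if c1 <= m:
            cds.append((100 + c1, 100 + min(c2, m)))
        if c2 > m:
            cds.append((150 + max(c1, m + 1), 150 + c2))
    else:  # single exon, reverse strand
        strand = "-"
        exons = [(101, 100 + L)]
        cds = [(101 + L - c2, 101 + L - c1)]
    attrs = (
        f'gene_id "{gene}"; transcript_id "{rec.transcript_id}"; '
        f'gene_name "{gene}";'
    )

    def line(feature: str, start: int, end: int) -> str:
        return (
            f"{chrom}\triboscope_sim\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t"
            f"{attrs}\n"
        )

    out = [line("transcript", exons[0][0], exons[-1][1])]
    for s, e in exons:
        out.append(line("exon", s, e))
    for s, e in cds:
        out.append(line("CDS", s, e))
    return out


@dataclass
class SimulatedFootprints:
    store: EndCountStore  # truth end counts, identical to quantifying the SAM
    asite_density: dict[str, np.ndarray]  # truth per-position A-site counts
    reads_per_transcript: dict[str, int]

    def write_truth(self, path: str | Path) -> None:
        payload = {
            "reads_per_transcript": self.reads_per_transcript,
            "asite_density": {
                t: v.tolist() for t, v in self.asite_density.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def simulate_footprints(
    reference: Reference,
    config: SimulationConfig,
    sam_path: str | Path | None = None,
    *,
    fold_changes: dict[str, float] | None = None,
    library_scale: float = 1.0,
    condition_tag: int = 0,
    sample_id: str = "sim",
) -> SimulatedFootprints:
    """Sample footprints over the CDS of each transcript and emit a SAM.

    Per-transcript expected read counts follow a mean-one lognormal expression
    level times ``n_reads / n_transcripts`` (optionally times a per-transcript
    fold change and a library scale), realised as Poisson counts.  For each
    read: with probability ``initiation_fraction`` the ribosome is paused at
    initiation (A-site on codon 2); otherwise the A-site codon is uniform over
    the CDS.  A phase error of 1 − in_frame_fraction is split evenly between
    the two off-frames.  The 5′ end is the A-site minus the per-length A-site
    distance; the read sequence is copied from the transcript.
    """
    config.validate()
    lengths = np.array(sorted(config.read_lengths))
    probs = np.array([config.read_lengths[int(l)] for l in lengths])
    probs = probs / probs.sum()
    p = config.in_frame_fraction
    phase_probs = np.array([p, (1 - p) / 2, (1 - p) / 2])

    store = EndCountStore(
        sample_id=sample_id,
        sequence_type="riboseq",
        assembly=reference.assembly,
        min_read_length=int(lengths.min()),
    )
    density: dict[str, np.ndarray] = {}
    n_per_tx: dict[str, int] = {}
    alignments: list[tuple[str, str, int, str]] = []  # (qname, tid, pos5, seq)

    ids = list(reference.records)
    nested_by_tid: dict[str, dict] = {}
    spec = config.nested_orf
    if spec is not None and spec.transcript_index < len(ids):
        tid = ids[spec.transcript_index]
        rec = reference[tid]
        q = rec.cds_start + 3 * spec.start_codon_index + 1
        nested_by_tid[tid] = {
            "start": q,
            "n_codons": spec.n_codons,
            "density": spec.density,
        }

    mean_per_tx = config.n_reads / max(len(ids), 1)
    sigma = config.expression_sigma
    for i, tid in enumerate(ids):
        rec = reference[tid]
        if not rec.is_coding:
            n_per_tx[tid] = 0
            density[tid] = np.zeros(rec.length, dtype=np.int64)
            continue
        expr_rng = _transcript_rng(config.seed, 7, i)  # shared across conditions
        expr = float(np.exp(sigma * expr_rng.normal() - sigma**2 / 2))
        rng = _transcript_rng(config.seed, 11 + condition_tag, i)
        fc = (fold_changes or {}).get(tid, 1.0)
        n = int(rng.poisson(mean_per_tx * expr * fc * library_scale))
        n_per_tx[tid] = n
        dens = np.zeros(rec.length, dtype=np.int64)
        n_codons = (rec.cds_stop - rec.cds_start) // 3
        nested = nested_by_tid.get(tid)
        for j in range(n):
            u = rng.random()
            if nested is not None and u < nested["density"]:
                k = int(rng.integers(0, nested["n_codons"]))
                base = nested["start"] + 3 * k
            elif rng.random() < config.initiation_fraction:
                base = rec.cds_start + 3  # A-site on codon 2, P-site at the start
            else:
                k = int(rng.integers(0, n_codons))
                base = rec.cds_start + 3 * k
            phase = int(rng.choice(3, p=phase_probs))
            asite = min(base + phase, rec.cds_stop - 1) if nested is None else base + phase
            length = int(rng.choice(lengths, p=probs))
            pos5 = asite - config.asite_offset(length)
            pos3 = pos5 + length - 1
            if pos5 < 1 or pos3 > rec.length:
                # geometry guarantees this cannot happen; guard anyway
                continue
            dens[asite - 1] += 1
            store.add(tid, length, pos5, FIVE_PRIME, UNAMBIGUOUS)
            store.add(tid, length, pos3, THREE_PRIME, UNAMBIGUOUS)
            store.total_retained_reads += 1
            if sam_path is not None:
                alignments.append(
                    (
                        f"r_{tid}_{condition_tag}_{j}",
                        tid,
                        pos5,
                        rec.sequence[pos5 - 1 : pos3],
                    )
                )
        density[tid] = dens

    if sam_path is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": tid, "LN": reference[tid].length} for tid in ids
            ],
        }
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            for qname, tid, pos5, seq in alignments:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.query_sequence = seq
                a.flag = 0
                a.reference_name = tid
                a.reference_start = pos5 - 1
                a.mapping_quality = 42
                a.cigarstring = f"{len(seq)}M"
                out.write(a)

    return SimulatedFootprints(
        store=store, asite_density=density, reads_per_transcript=n_per_tx
    )


def simulate_differential_counts(
    n_transcripts: int = 3000,
    mean_log: float = 4.0,
    sigma_log: float = 1.0,
    fold_changes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, int], dict[str, int], dict[str, float]]:
    """Two-condition Poisson count maps around shared lognormal means.

    Condition B's mean is multiplied by the transcript's fold change (default
    1: a null).  Returns (counts_a, counts_b, fold change truth).
    """
    rng = np.random.default_rng([seed % (2**31), 99])
    ids = [f"TX{i:05d}" for i in range(n_transcripts)]
    mu = np.exp(rng.normal(mean_log, sigma_log, size=n_transcripts))
    fc = np.array([(fold_changes or {}).get(t, 1.0) for t in ids])
    a = rng.poisson(mu)
    b = rng.poisson(mu * fc)
    return (
        dict(zip(ids, a.astype(int).tolist())),
        dict(zip(ids, b.astype(int).tolist())),
        dict(zip(ids, fc.tolist())),
    )
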