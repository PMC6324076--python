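import pysam
import pytest

from riboscope.reference import Reference, TranscriptRecord
from riboscope.simulate import (
    SimulationConfig,
    simulate_footprints,
    simulate_transcriptome,
)


def write_sam(path, reads, references):
    """Write alignments given as (qname, tid, pos_1based, seq, flag) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": tid, "LN": length} for tid, length in references],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, tid, pos, seq, flag in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.query_sequence = seq
            a.flag = flag
            a.reference_name = tid
            a.reference_start = pos - 1
            a.mapping_quality = 42
            a.cigarstring = f"{len(seq)}M"
            out.write(a)
    return path


@pytest.fixture
def toy_reference():
    """Two transcripts: one coding (cds 21..81), one non-coding."""
    body = "GCT" * 19  # 19 codons, no starts/stops
    seq = "C" * 20 + "ATG" + body + "TGA" + "A" * 37  # length 120, cds 21..81
    records = {
        "T1": TranscriptRecord("T1", "GENE1", seq, cds_start=21, cds_stop=81),
        "T2": TranscriptRecord("T2", "GENE2", "ACGT" * 30),
    }
    return Reference(records=records, assembly="toy")


@pytest.fixture(scope="session")
def basic_sim(tmp_path_factory):
    """Simulated transcriptome + footprints + quantified store (shared)."""
    from riboscope.countstore import quantify_alignments
    from riboscope.reference import build_reference

    cfg = SimulationConfig(n_transcripts=10, n_reads=8000, seed=11)
    tx = simulate_transcriptome(cfg)
    out = tmp_path_factory.mktemp("basic_sim")
    fasta, gtf, truth = tx.write(out)
    sam = out / "footprints.sam"
    fp = simulate_footprints(tx.reference, cfg, sam)
    reference = build_reference(fasta, gtf, assembly=cfg.assembly)
    store = quantify_alignments(sam, reference, 25)
    return {
        "config": cfg,
        "tx": tx,
        "reference": reference,
        "fasta": fasta,
        "gtf": gtf,
        "sam": sam,
        "footprints": fp,
        "store": store,
        "dir": out,
    }
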