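"""Metagene aggregation and the peak±3 A-site offset rule."""

import numpy as np
import pytest

from riboscope.countstore import FIVE_PRIME, THREE_PRIME, EndCountStore
from riboscope.metagene import (
    MetageneProfile,
    Offset,
    OffsetTable,
    apply_offsets,
    infer_offsets,
    metagene_profile,
)
from riboscope.reference import Reference, TranscriptRecord
from riboscope.simulate import (
    SimulationConfig,
    simulate_footprints,
    simulate_transcriptome,
)


def spike_profile(end, window, length, rel, count=100):
    prof = MetageneProfile(anchor="start_codon", end=end, window=window)
    arr = np.zeros(2 * window + 1, dtype=np.int64)
    arr[rel + window] = count
    prof.counts[length] = arr
    return prof


@pytest.fixture
def small_coding_reference():
    body = "GCT" * 19
    seq = "C" * 20 + "ATG" + body + "TGA" + "A" * 37  # cds 21..81, length 120
    rec = TranscriptRecord("T1", "G1", seq, cds_start=21, cds_stop=81)
    return Reference(records={"T1": rec}, assembly="toy")


class TestMetageneProfile:
    def test_relative_position_is_simple_subtraction(self, small_coding_reference):
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 9, FIVE_PRIME)
        prof = metagene_profile(
            store, small_coding_reference, end=FIVE_PRIME, window=20
        )
        arr = prof.array(30)
        assert arr[-12 + 20] == 1
        assert arr.sum() == 1

    def test_empty_store_gives_zero_profile(self, small_coding_reference):
        store = EndCountStore(assembly="toy")
        prof = metagene_profile(store, small_coding_reference, window=20)
        assert prof.combined().sum() == 0

    def test_no_coding_transcripts_is_hard_error(self):
        ref = Reference(
            records={"N": TranscriptRecord("N", "G", "ACGT" * 30)}, assembly="x"
        )
        with pytest.raises(ValueError, match="coding"):
            metagene_profile(EndCountStore(assembly="x"), ref)

    def test_transcripts_without_full_window_are_excluded(
        self, small_coding_reference
    ):
        # cds_start=21 leaves only 20 nt upstream: excluded at window=100
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 9, FIVE_PRIME)
        prof = metagene_profile(
            store, small_coding_reference, end=FIVE_PRIME, window=100
        )
        assert prof.combined().sum() == 0

    def test_simulated_five_prime_spike_lands_at_configured_distance(self):
        cfg = SimulationConfig(
            n_transcripts=6,
            n_reads=4000,
            seed=5,
            in_frame_fraction=1.0,
            initiation_fraction=0.3,
            asite_offsets=15,
        )
        tx = simulate_transcriptome(cfg)
        fp = simulate_footprints(tx.reference, cfg)
        prof = metagene_profile(fp.store, tx.reference, end=FIVE_PRIME)
        for length, arr in prof.counts.items():
            upstream = arr[: prof.window]
            # strongest upstream position: initiation A-site (codon 2) at -12
            assert np.argmax(upstream) - prof.window == -12

    def test_tsv_export_shape(self, small_coding_reference):
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 9, FIVE_PRIME)
        prof = metagene_profile(
            store, small_coding_reference, end=FIVE_PRIME, window=20
        )
        df = prof.to_frame()
        assert set(df.columns) == {"relative_position", "read_length", "count"}
        assert len(df) == 41
        assert df["count"].sum() == 1


class TestInferOffsets:
    def test_five_prime_peak_plus_three(self):
        mg5 = spike_profile(FIVE_PRIME, 100, 30, rel=-12)
        mg3 = spike_profile(THREE_PRIME, 100, 30, rel=17)
        table = infer_offsets(mg5, mg3)
        assert table.offsets[30].offset_5 == 15  # 12 + 3
        assert table.offsets[30].offset_3 == 14  # 17 - 3
        assert table.offsets[30].source == "inferred"

    def test_flat_profile_falls_back_with_warning(self):
        mg5 = MetageneProfile("start_codon", FIVE_PRIME, 100, {30: np.zeros(201, int)})
        mg3 = MetageneProfile("start_codon", THREE_PRIME, 100, {30: np.zeros(201, int)})
        with pytest.warns(UserWarning, match="fallback"):
            table = infer_offsets(mg5, mg3, fallback=15)
        assert table.offsets[30].offset_5 == 15
        assert table.offsets[30].offset_3 == 15
        assert table.offsets[30].source == "fallback"

    def test_tie_breaks_toward_smallest_distance(self):
        mg5 = spike_profile(FIVE_PRIME, 50, 28, rel=-15)
        mg5.counts[28][-9 + 50] = 100  # equal peak closer to the start
        mg3 = spike_profile(THREE_PRIME, 50, 28, rel=20)
        table = infer_offsets(mg5, mg3)
        assert table.offsets[28].offset_5 == 9 + 3

    def test_offset_bounds_guard_uses_fallback(self):
        # 3' peak at +2 would give a non-positive offset: fall back
        mg5 = spike_profile(FIVE_PRIME, 50, 30, rel=-12)
        mg3 = spike_profile(THREE_PRIME, 50, 30, rel=2)
        with pytest.warns(UserWarning):
            table = infer_offsets(mg5, mg3, fallback=15)
        assert table.offsets[30].offset_3 == 15

    def test_wrong_profile_ends_rejected(self):
        mg5 = spike_profile(FIVE_PRIME, 50, 30, rel=-12)
        with pytest.raises(ValueError):
            infer_offsets(mg5, mg5)

    def test_tsv_roundtrip(self, tmp_path):
        mg5 = spike_profile(FIVE_PRIME, 100, 30, rel=-12)
        mg3 = spike_profile(THREE_PRIME, 100, 30, rel=17)
        table = infer_offsets(mg5, mg3)
        table.to_tsv(tmp_path / "o.tsv")
        back = OffsetTable.from_tsv(tmp_path / "o.tsv")
        assert back.offsets[30].offset_5 == 15
        assert back.offsets[30].offset_3 == 14


class TestApplyOffsets:
    def test_single_count_shifted_by_offset(self):
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 10, FIVE_PRIME)
        table = OffsetTable(fallback=15)
        vec, dropped = apply_offsets(store, table, "T1", 120)
        assert vec[25 - 1] == 1 and vec.sum() == 1 and dropped == 0

    def test_empty_store_zero_vector(self):
        vec, dropped = apply_offsets(
            EndCountStore(assembly="toy"), OffsetTable(), "T1", 120
        )
        assert vec.sum() == 0 and dropped == 0

    def test_out_of_bounds_positions_tallied(self):
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 115, FIVE_PRIME)  # 115 + 15 > 120
        vec, dropped = apply_offsets(store, OffsetTable(fallback=15), "T1", 120)
        assert vec.sum() == 0 and dropped == 1

    def test_p_site_is_three_upstream_of_a_site(self):
        store = EndCountStore(assembly="toy")
        store.add("T1", 30, 10, FIVE_PRIME)
        table = OffsetTable(fallback=15)
        a, _ = apply_offsets(store, table, "T1", 120, site="a")
        p, _ = apply_offsets(store, table, "T1", 120, site="p")
        assert np.argmax(a) - np.argmax(p) == 3

    def test_three_prime_route_matches_five_prime_route(self, basic_sim):
        """5' and 3' ends of the same reads map to the same A-sites."""
        store = basic_sim["store"]
        ref = basic_sim["reference"]
        cfg = basic_sim["config"]
        table = OffsetTable(
            offsets={
                L: Offset(cfg.asite_offset(L), L - 1 - cfg.asite_offset(L))
                for L in range(25, 36)
            }
        )
        tid = ref.coding_ids()[0]
        v5, d5 = apply_offsets(store, table, tid, ref[tid].length, FIVE_PRIME)
        v3, d3 = apply_offsets(store, table, tid, ref[tid].length, THREE_PRIME)
        assert np.array_equal(v5, v3)

    def test_conservation_minus_drops(self, basic_sim):
        store = basic_sim["store"]
        ref = basic_sim["reference"]
        table = OffsetTable(fallback=15)
        total = 0
        for tid in ref:
            vec, dropped = apply_offsets(store, table, tid, ref[tid].length)
            total += vec.sum() + dropped
        assert total == store.total_retained_reads


class TestOffsetRecovery:
    def test_true_asite_distance_recovered_per_readlength(self):
        """With a dominant initiation peak the inferred 5' offset equals the
        configured 5'->A-site distance for every read length."""
        deltas = {L: 12 + (L % 4) for L in range(25, 36)}  # 12..15 nt A-site dist
        cfg = SimulationConfig(
            n_transcripts=8, n_reads=20_000, seed=2, asite_offsets=deltas,
            in_frame_fraction=0.7,
        )
        tx = simulate_transcriptome(cfg)
        fp = simulate_footprints(tx.reference, cfg)
        mg5 = metagene_profile(fp.store, tx.reference, end=FIVE_PRIME)
        mg3 = metagene_profile(fp.store, tx.reference, end=THREE_PRIME)
        table = infer_offsets(mg5, mg3)
        for L in range(25, 36):
            assert table.offsets[L].offset_5 == deltas[L]
            assert table.offsets[L].offset_3 == L - 1 - deltas[L]

    def test_adjusted_metagene_peaks_one_codon_into_cds(self, basic_sim):
        """Correct offsets put the initiation peak on codon 2 (rel +3)."""
        store = basic_sim["store"]
        ref = basic_sim["reference"]
        mg5 = metagene_profile(store, ref, end=FIVE_PRIME)
        mg3 = metagene_profile(store, ref, end=THREE_PRIME)
        table = infer_offsets(mg5, mg3)
        combined = np.zeros(201, dtype=np.int64)
        for tid in ref.coding_ids():
            rec = ref[tid]
            vec, _ = apply_offsets(store, table, tid, rec.length)
            lo = rec.cds_start - 1 - 100
            hi = rec.cds_start - 1 + 101
            if lo >= 0 and hi <= rec.length:
                combined += vec[lo:hi]
        assert np.argmax(combined) - 100 == 3
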