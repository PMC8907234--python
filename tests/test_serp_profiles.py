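"""Tracks -> densities -> combined replicates -> smoothed enrichment profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotransl.serp_profiles import (
    CombinedTrack,
    FootprintTrack,
    combine_replicates,
    enrichment_profile,
    gliding_average,
    load_position_counts,
    normalize_track,
    profiles_from_tracks,
    read_profile,
    write_profile,
)
from cotransl.synthetic_data import SerpSimSpec, simulate_footprints


def track(counts, lib=1_000_000, cond="total", rep=1, tid="T1"):
    return FootprintTrack(tid, f"{cond}_{rep}", cond, rep, np.asarray(counts), lib)


class TestLoadPositionCounts:
    def make_tsv(self, tmp_path, rows):
        path = tmp_path / "counts.tsv"
        pd.DataFrame(rows, columns=["transcript_id", "pos_nt", "count"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def test_first_codon_collects_first_three_nt(self, tmp_path):
        path = self.make_tsv(tmp_path, [("T1", 1, 2), ("T1", 2, 3), ("T1", 3, 4)])
        (t,) = load_position_counts(path, {"T1": 10})
        assert t.counts[0] == 9
        assert t.counts[1:].sum() == 0

    def test_out_of_orf_positions_dropped(self, tmp_path):
        path = self.make_tsv(tmp_path, [("T1", 31, 5), ("T1", 1, 1)])
        (t,) = load_position_counts(path, {"T1": 10})
        assert t.counts.sum() == 1  # nt 31 -> codon 11 falls off a 10-codon ORF

    def test_uniform_nt_coverage_gives_three_reads_per_codon(self, tmp_path):
        rows = [("T1", p, 3) for p in range(1, 31)]
        path = self.make_tsv(tmp_path, rows)
        (t,) = load_position_counts(path, {"T1": 10})
        assert (t.counts == 9).all()

    def test_unknown_transcript_raises_with_offender(self, tmp_path):
        path = self.make_tsv(tmp_path, [("MYSTERY", 1, 1)])
        with pytest.raises(KeyError, match="MYSTERY"):
            load_position_counts(path, {"T1": 10})

    def test_psite_offset_shifts_codon_assignment(self, tmp_path):
        path = self.make_tsv(tmp_path, [("T1", 1, 5)])
        (t,) = load_position_counts(path, {"T1": 10}, psite_offset=3)
        assert t.counts[1] == 5  # shifted onto codon 2


class TestNormalize:
    def test_unit_library_is_identity(self):
        t = track([2, 0, 2], lib=1_000_000)
        assert np.allclose(normalize_track(t), [2, 0, 2])

    def test_doubling_library_halves_density(self):
        t1 = track([5], lib=1_000_000)
        t2 = track([5], lib=2_000_000)
        assert np.allclose(normalize_track(t1), 2 * normalize_track(t2))
        assert np.allclose(normalize_track(t2), [2.5])

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            FootprintTrack("T1", "s", "total", 1, np.array([0]), 0)


class TestCombineReplicates:
    def test_identical_replicates_idempotent(self):
        reps = [track([1, 2, 3], rep=r) for r in (1, 2, 3)]
        combined = combine_replicates(reps)
        assert np.allclose(combined.density, normalize_track(reps[0]))
        assert combined.n_replicates == 3

    def test_mean_of_rpm(self):
        combined = combine_replicates([track([0, 2], rep=1), track([4, 2], rep=2)])
        assert np.allclose(combined.density, [2, 2])

    def test_single_replicate_unchanged(self):
        combined = combine_replicates([track([7, 0, 1])])
        assert np.allclose(combined.density, [7, 0, 1])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            combine_replicates([track([1, 2]), track([1, 2, 3], rep=2)])

    def test_pooled_mode_sums_counts_and_libraries(self):
        combined = combine_replicates(
            [track([0, 2], lib=100, rep=1), track([4, 2], lib=300, rep=2)], method="pooled"
        )
        assert np.allclose(combined.density, np.array([4, 4]) * 1e6 / 400)


class TestGlidingAverage:
    def test_constant_vector_unchanged(self):
        assert np.allclose(gliding_average(np.full(20, 3.3), 7), 3.3)

    def test_hand_computed_truncated_windows(self):
        out = gliding_average([0, 3, 0, 3, 0], 3)
        assert np.allclose(out, [1.5, 1, 2, 1, 1.5])

    def test_w1_identity(self):
        x = np.arange(10.0)
        assert np.allclose(gliding_average(x, 1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            gliding_average([1, 2, 3], 4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=50),
        st.sampled_from([1, 3, 5, 9]),
    )
    def test_matches_brute_force_windowed_mean(self, values, w):
        out = gliding_average(values, w)
        half = w // 2
        for i in range(len(values)):
            window = values[max(0, i - half) : i + half + 1]
            assert out[i] == pytest.approx(np.mean(window))


class TestEnrichmentProfile:
    def test_identical_ip_and_total_gives_unity(self):
        c = CombinedTrack("T1", "total", np.array([3.0, 4.0, 5.0]), 1)
        ci = CombinedTrack("T1", "IP", np.array([3.0, 4.0, 5.0]), 1)
        prof = enrichment_profile(ci, c, window=3, pseudocount=0.5)
        assert np.allclose(prof.enrichment, 1.0)

    def test_proportional_tracks_give_constant_k(self):
        base = np.array([2.0, 6.0, 4.0, 8.0])
        ci = CombinedTrack("T1", "IP", 3 * base, 1)
        ct = CombinedTrack("T1", "total", base, 1)
        prof = enrichment_profile(ci, ct, window=1, pseudocount=1e-9)
        assert np.allclose(prof.enrichment, 3.0, atol=1e-6)

    def test_zero_total_with_zero_pseudocount_raises(self):
        ci = CombinedTrack("T1", "IP", np.array([1.0, 1.0]), 1)
        ct = CombinedTrack("T1", "total", np.array([1.0, 0.0]), 1)
        with pytest.raises(ValueError, match="pseudocount"):
            enrichment_profile(ci, ct, window=1, pseudocount=0.0)

    def test_simulated_step_enrichment_ratio_in_range(self):
        spec = SerpSimSpec(
            n_transcripts=1,
            orf_lengths_codons=120,
            onset_codons=[50],
            enrichment_fold=4.0,
            mean_depth=50.0,
            nb_dispersion=0.05,
            n_replicates=4,
            seed=42,
        )
        profiles = profiles_from_tracks(
            simulate_footprints(spec), window=15, pseudocount=0.5
        )
        E = profiles["ORF0001"].enrichment
        ratio = E[59:90].mean() / E[:40].mean()
        assert 3.0 <= ratio <= 5.0

    def test_library_rescaling_invariance_of_profile_shape(self):
        # enrichment with alpha -> 0 is invariant to rescaling either library
        rng = np.random.default_rng(0)
        ip = rng.uniform(1, 10, 50)
        tot = rng.uniform(1, 10, 50)
        p1 = enrichment_profile(
            CombinedTrack("T", "IP", ip, 1), CombinedTrack("T", "total", tot, 1), 5, 1e-12
        )
        p2 = enrichment_profile(
            CombinedTrack("T", "IP", ip * 3.7, 1),
            CombinedTrack("T", "total", tot * 3.7, 1),
            5,
            1e-12,
        )
        assert np.allclose(p1.enrichment, p2.enrichment, rtol=1e-6)

    def test_combine_then_smooth_commutes_with_smooth_then_mean(self):
        rng = np.random.default_rng(3)
        reps = [track(rng.integers(0, 20, 40), rep=r) for r in (1, 2, 3)]
        combined = combine_replicates(reps)
        a = gliding_average(combined.density, 7)
        b = np.mean([gliding_average(normalize_track(t), 7) for t in reps], axis=0)
        assert np.allclose(a, b)


def test_profile_roundtrip(tmp_path, small_serp_spec):
    profiles = profiles_from_tracks(simulate_footprints(small_serp_spec))
    prof = profiles["ORF0001"]
    tsv = write_profile(prof, tmp_path)
    back = read_profile(tsv)
    assert back.transcript_id == prof.transcript_id
    assert back.window == prof.window
    assert np.allclose(back.enrichment, prof.enrichment)
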