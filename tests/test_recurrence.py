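import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scnalnc import recurrence as rc
from scnalnc import synthetic as syn
from scnalnc.models import (
    AMPLIFICATION,
    DELETION,
    Peak,
    PlantedAlteration,
    SegmentSet,
    ValidationError,
)
from tests.conftest import flat_segments


def bh_oracle(p):
    """Independent Benjamini–Hochberg step-up, straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestBuildMarkerTrack:
    def test_single_tumor_uniform_gain(self):
        segs = flat_segments({"T1": 1.0}, length=100_000)
        track = rc.build_marker_track(segs, bin_size=10_000, direction=AMPLIFICATION)
        assert np.allclose(track.table["frequency"], 1.0)
        assert np.allclose(track.table["amplitude"], 1.0)
        assert np.allclose(track.table["g_score"], 1.0)

    def test_g_is_frequency_times_amplitude(self):
        segs = flat_segments({"T1": 0.8, "T2": 0.0}, length=50_000)
        track = rc.build_marker_track(segs, bin_size=10_000, direction=AMPLIFICATION)
        assert np.allclose(track.table["frequency"], 0.5)
        assert np.allclose(track.table["amplitude"], 0.8)
        assert np.allclose(track.table["g_score"], 0.4)

    def test_all_zero_cohort_scores_zero(self):
        segs = flat_segments({f"T{i}": 0.0 for i in range(5)})
        for d in (AMPLIFICATION, DELETION):
            track = rc.build_marker_track(segs, direction=d)
            assert (track.table["g_score"] == 0).all()

    def test_direction_tracks_are_independent(self):
        """Deletion G on an amplification-only cohort is identically zero."""
        segs = flat_segments({"T1": 1.2, "T2": 0.9})
        del_track = rc.build_marker_track(segs, direction=DELETION)
        assert (del_track.table["g_score"] == 0).all()
        amp_track = rc.build_marker_track(segs, direction=AMPLIFICATION)
        assert (amp_track.table["g_score"] > 0).all()

    def test_no_tumors_is_an_error(self):
        segs = flat_segments({"N1": 0.0}, labels={"N1": "normal"})
        with pytest.raises(ValidationError, match="tumor"):
            rc.build_marker_track(segs)

    def test_normals_excluded_from_scoring(self):
        segs = flat_segments({"T1": 0.0, "N1": 2.0}, labels={"T1": "tumor", "N1": "normal"})
        track = rc.build_marker_track(segs, direction=AMPLIFICATION)
        assert (track.table["g_score"] == 0).all()


class TestPermutationNull:
    def test_seed_determinism(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        a = rc.permutation_null(track, n_perm=100, seed=5)
        b = rc.permutation_null(track, n_perm=100, seed=5)
        assert np.array_equal(a, b)

    def test_rejects_too_few_permutations(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        with pytest.raises(ValidationError):
            rc.permutation_null(track, n_perm=10, seed=1)

    def test_observed_max_below_null_tail_without_signal(self, genome):
        """No-signal cohorts: max observed G within the null's 99.9th pct."""
        hits = 0
        for s in range(10):
            segs, _ = syn.simulate_cohort(genome, [], n_tumor=60, n_normal=0, seed=500 + s)
            track = rc.build_marker_track(segs)
            null = rc.permutation_null(track, n_perm=100, seed=600 + s)
            hits += track.table["g_score"].max() <= np.quantile(null, 0.999)
        assert hits >= 9

    def test_planted_signal_exceeds_null_maximum(self, genome):
        alt = PlantedAlteration("chr1", 3_000_000, 3_500_000, AMPLIFICATION, 0.2, 1.5, 0.1)
        segs, _ = syn.simulate_cohort(genome, [alt], n_tumor=100, n_normal=0, seed=77)
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, n_perm=100, seed=78)
        assert track.table["g_score"].max() > null.max()


class TestEmpiricalQ:
    def test_p_and_q_bounds_and_bh_agreement(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, n_perm=100, seed=3)
        track = rc.empirical_q(track, null)
        p = track.table["p_value"].to_numpy()
        q = track.table["q_value"].to_numpy()
        assert ((p > 0) & (p <= 1)).all() and ((q > 0) & (q <= 1)).all()
        assert np.allclose(q, bh_oracle(p), atol=1e-12)

    def test_zero_score_markers_get_p_one(self):
        segs = flat_segments({"T1": 0.0, "T2": 0.0})
        track = rc.build_marker_track(segs)
        null = np.zeros(1000)
        track = rc.empirical_q(track, null)
        assert (track.table["p_value"] == 1).all()
        assert (track.table["q_value"] == 1).all()

    def test_empty_null_rejected(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        with pytest.raises(ValidationError):
            rc.empirical_q(track, np.array([]))

    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=30))
    def test_q_order_respects_p_order(self, p):
        q = bh_oracle(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallAlterations:
    def test_nothing_significant_gives_empty_list(self):
        segs = flat_segments({"T1": 0.0, "T2": 0.0})
        track = rc.build_marker_track(segs)
        track = rc.empirical_q(track, np.zeros(500))
        assert rc.call_alterations(track, np.zeros(500)) == []

    def test_single_planted_alteration_recovered(self, genome, planted_lnc, planted_cohort):
        segs, _, alt = planted_cohort
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, seed=12)
        track = rc.empirical_q(track, null)
        peaks = rc.call_alterations(track, null)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.direction == AMPLIFICATION and p.chromosome == alt.chromosome
        assert p.focal[0] < alt.end and alt.start < p.focal[1]
        assert p.q_value < 0.25

    def test_two_separated_alterations_give_two_peaks(self, genome):
        alts = [
            PlantedAlteration("chr1", 1_000_000, 1_400_000, AMPLIFICATION, 0.15, 1.5, 0.1),
            PlantedAlteration("chr1", 6_000_000, 6_400_000, AMPLIFICATION, 0.15, 1.5, 0.1),
        ]
        segs, _ = syn.simulate_cohort(genome, alts, seed=31)
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, seed=32)
        track = rc.empirical_q(track, null)
        peaks = rc.call_alterations(track, null)
        assert len(peaks) == 2
        for alt in alts:
            assert any(
                p.focal[0] < alt.end and alt.start < p.focal[1] for p in peaks
            )

    def test_peak_nesting_invariant(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, seed=41)
        track = rc.empirical_q(track, null)
        for p in rc.call_alterations(track, null):
            r, e, f = p.region, p.enlarged, p.focal
            assert r[0] <= e[0] <= f[0] < f[1] <= e[1] <= r[1]

    def test_requires_q_values(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        with pytest.raises(ValidationError, match="q values"):
            rc.call_alterations(track, None)


class TestPeelOff:
    def test_single_supporting_sample_zeroes_region(self):
        segs = flat_segments({"T1": 1.5, "T2": 0.0}, length=100_000)
        track = rc.build_marker_track(segs, bin_size=10_000)
        peak = Peak(
            AMPLIFICATION, "chr1", (0, 100_000), (0, 100_000), (0, 100_000),
            g_score=0.75, q_value=0.01, samples=["T1"],
        )
        residual = rc.peel_off(track, peak)
        assert (residual.table["g_score"] == 0).all()

    def test_never_increases_g(self, planted_cohort):
        segs, _, _ = planted_cohort
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, seed=51)
        track = rc.empirical_q(track, null)
        peaks = rc.call_alterations(track, null)
        residual = rc.peel_off(track, peaks[0])
        assert (
            residual.table["g_score"].to_numpy() <= track.table["g_score"].to_numpy() + 1e-12
        ).all()

    def test_colocated_independent_alterations_both_recovered(self, genome):
        """Two adjacent events forming one region: the second is found after
        the first peak's supporting samples are peeled off."""
        alts = [
            PlantedAlteration("chr2", 2_000_000, 2_150_000, AMPLIFICATION, 0.20, 1.5, 0.1),
            PlantedAlteration("chr2", 2_150_000, 2_300_000, AMPLIFICATION, 0.10, 2.0, 0.1),
        ]
        segs, carriers = syn.simulate_cohort(genome, alts, seed=61)
        track = rc.build_marker_track(segs)
        null = rc.permutation_null(track, seed=62)
        track = rc.empirical_q(track, null)
        peaks = rc.call_alterations(track, null)
        assert len(peaks) >= 2
        for alt in alts:
            assert any(
                p.focal[0] < alt.end and alt.start < p.focal[1] for p in peaks
            )
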