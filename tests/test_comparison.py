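"""Correlation, stratified means, class-binned averages, two-state overlap
and the prediction-rate sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbneq.comparison import (
    AlignmentError,
    InsufficientDataError,
    PairedSeries,
    UndefinedCorrelationError,
    class_binned_averages,
    compare,
    correlation,
    pair,
    prediction_rate_sweep,
    stratified_means,
    two_state_overlap,
)
from pbneq.neq_profile import NeqProfile, classify
from pbneq.predictor_io import ScoreTrack, binarize
from pbneq.synthetic import synth_score_track


def _profile(values, positions=None):
    v = np.asarray(values, dtype=float)
    pos = np.arange(1, len(v) + 1) if positions is None else np.asarray(positions)
    return NeqProfile(positions=pos, neq=v, classes=classify(v))


def _track(scores, positions=None, states=None, name="toy"):
    s = np.asarray(scores, dtype=float)
    pos = np.arange(1, len(s) + 1) if positions is None else np.asarray(positions)
    return ScoreTrack(name, pos, np.full(len(s), "A"), s, states)


def _series(neq_vals, scores):
    return PairedSeries(
        positions=np.arange(1, len(neq_vals) + 1),
        neq=np.asarray(neq_vals, float),
        scores=np.asarray(scores, float),
    )


class TestPair:
    def test_undefined_positions_dropped(self):
        prof = _profile([1, 2, np.nan, 4, 5, np.nan, 7, 8, 9, 10])
        track = _track(np.linspace(0, 1, 10))
        s = pair(prof, track)
        assert len(s) == 8
        assert s.n_dropped == 2

    def test_disjoint_ranges_raise(self):
        prof = _profile([1, 2, 3], positions=[1, 2, 3])
        track = _track([0.1, 0.2, 0.3], positions=[50, 51, 52])
        with pytest.raises(InsufficientDataError):
            pair(prof, track)

    def test_identical_index_sets_drop_nothing(self):
        prof = _profile([1, 2, 3, 4])
        track = _track([0.1, 0.2, 0.3, 0.4])
        s = pair(prof, track)
        assert len(s) == 4 and s.n_dropped == 0

    def test_offset_alignment(self):
        prof = _profile([1, 2, 3, 4], positions=[11, 12, 13, 14])
        track = _track([0.1, 0.2, 0.3, 0.4], positions=[1, 2, 3, 4])
        s = pair(prof, track, offset=10)
        assert len(s) == 4


class TestCorrelation:
    def test_affine_increasing_is_one(self):
        s = _series([1, 2, 5, 9], np.array([1, 2, 5, 9]) * 0.1 + 0.01)
        assert correlation(s) == pytest.approx(1.0)

    def test_affine_decreasing_is_minus_one(self):
        s = _series([1, 2, 5, 9], 1.0 - np.array([1, 2, 5, 9]) * 0.1)
        assert correlation(s) == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation(_series([1, 2, 3], [0.5, 0.5, 0.5]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation(_series([1, 2], [0.1, 0.2]))

    def test_recovers_generator_target(self):
        rng = np.random.default_rng(21)
        neq_vals = np.clip(1 + rng.gamma(2.0, 2.5, 1000), 1, 16)
        track = synth_score_track(neq_vals, 0.35, seed=22)
        prof = _profile(neq_vals)
        r = correlation(pair(prof, track))
        assert r == pytest.approx(0.35, abs=0.06)

    @given(
        st.floats(0.01, 10), st.floats(-5, 5),
        st.floats(0.01, 10), st.floats(-5, 5),
    )
    def test_affine_invariance_and_symmetry(self, a, b, c, d):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.8, size=40)
        r = correlation((x, y))
        assert correlation((a * x + b, c * y + d)) == pytest.approx(r, abs=1e-6)
        assert correlation((y, x)) == pytest.approx(r)
        assert -1.0 <= r <= 1.0


class TestStratifiedMeans:
    def test_hand_built_strata(self):
        s = _series(
            [1.0, 2.0, 5.0, 6.5, 9.0, 12.0],
            [0.10, 0.20, 0.40, 0.60, 0.70, 0.90],
        )
        df = stratified_means(s)
        assert list(df["count"]) == [2, 2, 2]
        assert df["mean_score"].tolist() == pytest.approx([0.15, 0.50, 0.80])

    def test_boundary_values_inclusive_in_middle(self):
        s = _series([4.0, 8.0, 1.0], [0.3, 0.5, 0.1])
        df = stratified_means(s)
        assert df.loc[1, "count"] == 2  # 4 and 8 both in the middle stratum

    def test_single_populated_stratum(self):
        s = _series([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        df = stratified_means(s)
        assert df.loc[0, "count"] == 3
        assert df.loc[1, "count"] == 0 and np.isnan(df.loc[1, "mean_score"])

    def test_constant_scores_constant_means(self):
        s = _series([1.0, 5.0, 9.0], [0.5, 0.5, 0.5])
        df = stratified_means(s)
        assert df["mean_score"].tolist() == pytest.approx([0.5, 0.5, 0.5])


class TestClassBinnedAverages:
    def test_single_class_insufficient(self):
        s = _series([1.1, 1.5, 1.9, 1.2], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(InsufficientDataError):
            class_binned_averages(s)

    def test_monotone_means_high_correlation(self):
        neq_vals = np.concatenate([np.full(5, k + 0.5) for k in range(1, 12)])
        scores = np.concatenate([np.full(5, 0.05 * k) for k in range(1, 12)])
        df, r = class_binned_averages(_series(neq_vals, scores))
        assert r > 0.9
        assert df["count"].sum() == len(neq_vals)

    def test_top_class_collects_twelve_and_higher(self):
        s = _series([1.5, 5.0, 12.0, 15.9], [0.1, 0.4, 0.8, 0.9])
        df, _ = class_binned_averages(s)
        top = df[df["class_lower"] == 12.0].iloc[0]
        assert top["count"] == 2
        assert top["mean_score"] == pytest.approx(0.85)

    def test_aggregation_beats_pairwise_correlation(self):
        """On a noisy monotone score model, class-level correlation exceeds
        the pair-level one: averaging within classes removes noise."""
        rng = np.random.default_rng(8)
        neq_vals = np.clip(1 + rng.gamma(2.0, 2.5, 1000), 1, 16)
        track = synth_score_track(neq_vals, 0.35, seed=9)
        series = pair(_profile(neq_vals), track)
        r_pair = correlation(series)
        _, r_class = class_binned_averages(series)
        assert r_class > r_pair


class TestTwoStateOverlap:
    def test_identical_tracks(self):
        t = _track([0.9, 0.8, 0.1], states=list("DDO"))
        ov = two_state_overlap(t, t)
        assert ov["total_agreement"] == 1.0

    def test_complementary_tracks(self):
        a = _track([0.9, 0.9, 0.1], states=list("DDO"), name="a")
        b = _track([0.1, 0.1, 0.9], states=list("OOD"), name="b")
        assert two_state_overlap(a, b)["total_agreement"] == 0.0

    def test_toy_decomposition(self):
        a = _track(np.full(10, 0.5), states=list("DDDOOOOODO"), name="a")
        b = _track(np.full(10, 0.5), states=list("DDDOOOOOOD"), name="b")
        ov = two_state_overlap(a, b)
        assert ov["common_disorder"] == pytest.approx(0.3)
        assert ov["common_order"] == pytest.approx(0.5)
        assert ov["total_agreement"] == pytest.approx(0.8)

    def test_decomposition_sums_exactly(self, rng):
        a = binarize(_track(rng.random(200), name="a"))
        b = binarize(_track(rng.random(200), name="b"))
        ov = two_state_overlap(a, b)
        assert ov["total_agreement"] == ov["common_disorder"] + ov["common_order"]

    def test_missing_states_rejected(self):
        a = _track([0.5, 0.5, 0.5])
        with pytest.raises(AlignmentError):
            two_state_overlap(a, a)


class TestPredictionRateSweep:
    def test_all_order_against_fully_rigid(self):
        prof = _profile(np.ones(20))
        track = _track(np.zeros(20), states=["O"] * 20)
        df = prediction_rate_sweep(prof, track)
        assert (df["prediction_rate"] == 1.0).all()

    def test_perfect_oracle_at_threshold_eight(self, rng):
        neq_vals = rng.uniform(1, 16, 500)
        states = np.where(neq_vals > 8.0, "D", "O")
        prof = _profile(neq_vals)
        track = _track(np.where(states == "D", 0.9, 0.1), states=states)
        df = prediction_rate_sweep(prof, track)
        assert df.loc[df["threshold"] == 8.0, "prediction_rate"].item() == 1.0

    def test_independent_balanced_near_half(self):
        rng = np.random.default_rng(17)
        neq_vals = rng.uniform(1, 15, 1000)  # truth at t=8 roughly balanced
        states = rng.choice(["D", "O"], 1000)
        prof = _profile(neq_vals)
        track = _track(np.full(1000, 0.5), states=states)
        df = prediction_rate_sweep(prof, track)
        rate = df.loc[df["threshold"] == 8.0, "prediction_rate"].item()
        assert rate == pytest.approx(0.5, abs=0.05)

    def test_equality_counts_as_order(self):
        prof = _profile([1.0, 1.0, 1.0])
        track = _track([0.1] * 3, states=["O"] * 3)
        df = prediction_rate_sweep(prof, track, thresholds=(1.0,))
        assert df["prediction_rate"].item() == 1.0
        assert df["true_order_fraction"].item() == 1.0

    def test_permutation_invariance(self, rng):
        """Rates depend on the position -> (N_eq, state) mapping, not on the
        storage order of the profile arrays."""
        neq_vals = rng.uniform(1, 16, 50)
        states = rng.choice(["D", "O"], 50)
        prof = _profile(neq_vals)
        track = _track(np.full(50, 0.5), states=states)
        base = prediction_rate_sweep(prof, track)["prediction_rate"].to_numpy()
        perm = rng.permutation(50)
        prof2 = NeqProfile(
            positions=prof.positions[perm], neq=neq_vals[perm],
            classes=classify(neq_vals[perm]),
        )
        again = prediction_rate_sweep(prof2, track)["prediction_rate"].to_numpy()
        np.testing.assert_allclose(base, again)

    def test_truth_balance_reported(self):
        prof = _profile([1, 2, 9, 10, 12])
        track = _track(np.full(5, 0.5), states=["O"] * 5)
        df = prediction_rate_sweep(prof, track, thresholds=(8.0,))
        assert df["true_disorder_fraction"].item() == pytest.approx(0.6)
        assert df["true_order_fraction"].item() == pytest.approx(0.4)


class TestCompareOrchestration:
    def test_full_report(self, rng):
        neq_vals = np.clip(1 + rng.gamma(2.0, 2.5, 300), 1, 16)
        prof = _profile(neq_vals)
        t1 = synth_score_track(neq_vals, 0.6, seed=1, predictor="p1")
        t2 = synth_score_track(neq_vals, 0.4, seed=2, predictor="p2")
        report = compare(prof, [t1, t2])
        assert set(report.correlations["y"]) >= {"p1", "p2"}
        assert len(report.sweeps) == 24
        assert (report.overlaps["total_agreement"] <= 1.0).all()
        assert "correlation_neq_p1" in report.summary

    def test_no_tracks_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare(_profile([1, 2, 3]), [])
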