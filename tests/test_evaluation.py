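import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neutroforecast import (
    Scenario,
    classify,
    first_event_day,
    rmse,
    rmse_pct,
    sensitivity_specificity,
    summarize_trajectory,
)
from neutroforecast.evaluation import accuracy_distribution
from neutroforecast.ode import Trajectory


def make_traj(day_points, anc_points, anc0=5.0, horizon_days=42.0):
    """Piecewise-linear toy trajectory on a dense grid."""
    t = np.arange(0.0, horizon_days * 24.0 + 1e-9, 2.4)
    circ = np.interp(t / 24.0, day_points, anc_points)
    return Trajectory(times=t, circ=circ, anc0=anc0)


class TestSummaryVariables:
    def test_v_shape(self):
        traj = make_traj([0, 7, 17, 42], [5.0, 1.0, 5.0, 5.0])
        s = summarize_trajectory(traj)
        assert s.nadir_time == pytest.approx(7.0, abs=0.1)
        assert s.nadir_anc == pytest.approx(1.0, abs=0.02)
        assert s.recovery_time == pytest.approx(17.0, abs=0.1)
        assert s.recovery_reached

    def test_flat_trajectory_has_no_dip(self):
        traj = make_traj([0, 42], [5.0, 5.0])
        s = summarize_trajectory(traj)
        assert s.nadir_time == 0.0
        assert not s.recovery_reached

    def test_recovery_not_reached_within_horizon(self):
        traj = make_traj([0, 7, 42], [5.0, 1.0, 4.0])
        s = summarize_trajectory(traj)
        assert np.isnan(s.recovery_time)

    def test_recovery_against_supplied_baseline(self):
        traj = make_traj([0, 7, 42], [5.0, 1.0, 4.5])
        s = summarize_trajectory(traj, anc0_i=4.0)
        assert s.recovery_reached
        assert s.recovery_time > s.nadir_time

    def test_short_grid_rejected(self):
        t = np.arange(0.0, 10 * 24.0, 2.4)
        with pytest.raises(ValueError):
            summarize_trajectory(Trajectory(times=t, circ=np.full(t.shape, 5.0), anc0=5.0))


class TestRMSE:
    def test_exact_prediction_is_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse_pct([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_examples(self):
        assert rmse([3.0, 5.0], [1.0, 2.0]) == pytest.approx(np.sqrt(13 / 2))
        assert rmse_pct([2.0], [1.0]) == pytest.approx(100.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse_pct([1.0, 2.0], [0.0, 1.0])  # zero truth

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50), st.floats(0.1, 50)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_brute_force_sums(self, pairs):
        pred = np.array([a for a, _ in pairs])
        truth = np.array([b for _, b in pairs])
        brute = np.sqrt(sum((p - t) ** 2 for p, t in pairs) / len(pairs))
        brute_pct = np.sqrt(sum(((p - t) / t) ** 2 for p, t in pairs) / len(pairs)) * 100
        assert rmse(pred, truth) == pytest.approx(brute, rel=1e-12, abs=1e-12)
        assert rmse_pct(pred, truth) == pytest.approx(brute_pct, rel=1e-12, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "minimum, threshold, strict, expected",
        [
            (0.49, 0.5, True, True),
            (0.5, 0.5, True, False),   # strict boundary
            (0.1, 0.1, False, True),   # non-strict boundary
            (0.11, 0.1, False, False),
        ],
    )
    def test_threshold_boundaries(self, minimum, threshold, strict, expected):
        traj = make_traj([0, 7, 17, 42], [5.0, minimum, 5.0, 5.0])
        assert classify(traj, threshold, strict) is expected

    def test_crossing_after_cycle_end_ignored(self):
        traj = make_traj([0, 21, 25, 42], [5.0, 2.0, 0.3, 5.0])
        assert classify(traj, 0.5, True, window_days=(0, 21)) is False

    def test_first_event_day_on_daily_grid(self):
        traj = make_traj([0, 5, 9, 17, 42], [5.0, 0.45, 0.45, 5.0, 5.0])
        assert first_event_day(traj, 0.5, True) == 5.0
        assert np.isnan(first_event_day(traj, 0.1, False))

    def test_confusion_matrix_identities(self):
        truth = [True] * 90 + [False] * 10
        pred = [True] * 80 + [False] * 10 + [False] * 5 + [True] * 5
        cr = sensitivity_specificity(truth, pred)
        assert cr.tp + cr.fn == 90 and cr.tn + cr.fp == 10
        assert cr.sensitivity == pytest.approx(cr.tp / 90)
        assert cr.specificity == pytest.approx(cr.tn / 10)
        assert cr.n == 100

    def test_perfect_prediction(self):
        labels = [True, False, True, True]
        cr = sensitivity_specificity(labels, labels)
        assert cr.sensitivity == 1.0 and cr.specificity == 1.0

    def test_undefined_metric_reported_missing(self):
        cr = sensitivity_specificity([True, True], [True, False])
        assert np.isnan(cr.specificity)
        assert cr.sensitivity == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        truth = rng.random(200) < 0.6
        pred = rng.random(200) < 0.5
        perm = rng.permutation(200)
        a = sensitivity_specificity(truth, pred)
        b = sensitivity_specificity(truth[perm], pred[perm])
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


class _StubFit:
    converged = True

    def __init__(self, ratios_by_day):
        self._r = ratios_by_day

    def accuracy_ratio(self, patient, day):
        return self._r[day]


class TestAccuracyDistribution:
    def test_perfect_fits_give_unit_percentiles(self):
        fits = [_StubFit({21.0: 1.0}) for _ in range(10)]
        tab = accuracy_distribution(fits, [None] * 10, Scenario("daily", 7), [21.0])
        row = tab.iloc[0]
        for col in ("p2.5", "p25", "p50", "p75", "p97.5"):
            assert row[col] == pytest.approx(1.0)

    def test_percentiles_match_sorted_array_oracle(self, rng):
        vals = rng.lognormal(0.0, 1.0, 101)
        fits = [_StubFit({21.0: v}) for v in vals]
        tab = accuracy_distribution(fits, [None] * 101, Scenario("daily", 7), [21.0])
        s = np.sort(vals)
        # brute-force linear-interpolated order statistics
        for q, col in ((2.5, "p2.5"), (50.0, "p50"), (97.5, "p97.5")):
            pos = q / 100.0 * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expect = s[lo] + (pos - lo) * (s[hi] - s[lo])
            assert tab.iloc[0][col] == pytest.approx(expect, rel=1e-12)
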