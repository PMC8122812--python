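"""Error metrics against brute-force oracles; BHS/AAMI worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulse2abp.evaluate import (
    aami_check,
    bhs_grade,
    bp_correlation,
    error_std,
    evaluate_run,
    mae,
    rmse,
)


def _errors_with_percentages(f5: float, f10: float, f15: float, n: int = 1000):
    """Absolute-error set whose cumulative fractions at 5/10/15 mmHg are
    exactly the requested ones."""
    k5 = round(f5 * n)
    k10 = round(f10 * n)
    k15 = round(f15 * n)
    return np.concatenate([
        np.full(k5, 3.0),
        np.full(k10 - k5, 8.0),
        np.full(k15 - k10, 13.0),
        np.full(n - k15, 20.0),
    ])


def _errors_with_mae_std(target_mae: float, target_std: float, n: int = 2000):
    """Signed errors with (near-)exact mean absolute error and population
    standard deviation."""
    if target_mae > target_std:
        # biased two-point set: mean M, spread S
        half = n // 2
        return np.concatenate([
            np.full(half, target_mae + target_std),
            np.full(n - half, target_mae - target_std),
        ])
    # zero-mean set: a fraction p at magnitude x plus zeros, with
    # p = M^2/S^2 and x = S^2/M
    p = (target_mae / target_std) ** 2
    k = max(2, round(p * n))
    k -= k % 2
    x = n * target_mae / k
    return np.concatenate([np.full(k // 2, x), np.full(k // 2, -x),
                           np.zeros(n - k)])


class TestPointMetrics:
    def test_hand_examples(self):
        assert mae(np.zeros(3)) == 0.0
        assert mae(np.array([3.0, -4.0])) == 3.5
        assert rmse(np.zeros(2)) == 0.0
        assert rmse(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_metrics_match_elementwise_brute_force(self, rng):
        e = rng.normal(0, 5, 10_000)
        acc_abs = 0.0
        acc_sq = 0.0
        for v in e:
            acc_abs += abs(v)
            acc_sq += v * v
        assert mae(e) == pytest.approx(acc_abs / e.size, abs=1e-10)
        assert rmse(e) == pytest.approx(np.sqrt(acc_sq / e.size), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rmse_dominates_mae(self, seed):
        e = np.random.default_rng(seed).normal(0, 10, 47)
        assert rmse(e) >= mae(e)

    def test_empty_error_set_rejected(self):
        for metric in (mae, rmse, error_std):
            with pytest.raises(ValueError):
                metric(np.array([]))


class TestBhsGrade:
    def test_published_sbp_and_dbp_rows_grade_a(self):
        """Cumulative percentages reported for this model family (SBP
        70.6/94.1/98.6, DBP 91.1/99.1/99.8) meet the grade-A rows."""
        sbp_errors = _errors_with_percentages(0.706, 0.941, 0.986)
        dbp_errors = _errors_with_percentages(0.911, 0.991, 0.998)
        for errors, pcts in ((sbp_errors, (70.6, 94.1, 98.6)),
                             (dbp_errors, (91.1, 99.1, 99.8))):
            res = bhs_grade(errors)
            assert res.grade == "A"
            assert res.pct_le_5 == pytest.approx(pcts[0], abs=0.05)
            assert res.pct_le_10 == pytest.approx(pcts[1], abs=0.05)
            assert res.pct_le_15 == pytest.approx(pcts[2], abs=0.05)

    def test_constructed_20_sample_set_grades_b(self):
        # 11/20 <= 5, 16/20 <= 10, 18/20 <= 15 -> (55%, 80%, 90%)
        errors = np.concatenate([
            np.full(11, 4.0), np.full(5, 9.0), np.full(2, 14.0), np.full(2, 20.0),
        ])
        res = bhs_grade(errors)
        assert (res.pct_le_5, res.pct_le_10, res.pct_le_15) == (55.0, 80.0, 90.0)
        assert res.grade == "B"

    def test_exact_grade_a_boundary_percentages_award_a(self):
        errors = _errors_with_percentages(0.60, 0.85, 0.95, n=100)
        assert bhs_grade(errors).grade == "A"

    def test_error_exactly_on_threshold_counts_within(self):
        res = bhs_grade(np.full(10, 5.0))
        assert res.pct_le_5 == 100.0

    def test_below_grade_c_fails(self):
        res = bhs_grade(np.full(10, 30.0))
        assert res.grade == "fail"

    def test_monotone_under_scaling_and_zero_padding(self):
        base = np.abs(np.random.default_rng(3).normal(0, 6, 200))
        g0 = bhs_grade(base).grade
        padded = bhs_grade(np.append(base, 0.0)).grade
        scaled = bhs_grade(2.0 * base).grade
        order = {"A": 0, "B": 1, "C": 2, "fail": 3}
        assert order[padded] <= order[g0]
        assert order[scaled] >= order[g0]

    def test_cumulative_percentages_are_monotone(self):
        res = bhs_grade(np.abs(np.random.default_rng(1).normal(0, 8, 500)))
        assert 0 <= res.pct_le_5 <= res.pct_le_10 <= res.pct_le_15 <= 100


class TestAamiCheck:
    def test_published_rows_pass(self):
        sbp = _errors_with_mae_std(4.05, 4.60, n=5289)
        res = aami_check(sbp, n_subjects=5289)
        assert res.passed
        assert res.mae == pytest.approx(4.05, abs=0.02)
        assert res.std == pytest.approx(4.60, abs=0.02)
        dbp = _errors_with_mae_std(2.41, 3.11, n=5289)
        assert aami_check(dbp, n_subjects=5289).passed

    @pytest.mark.parametrize(
        "target_mae, target_std, n, expected",
        [
            (5.0, 4.0, 100, False),   # mae must be strictly below 5
            (4.0, 8.0, 100, False),   # std must be strictly below 8
            (4.0, 4.0, 85, False),    # needs strictly more than 85 subjects
            (4.0, 4.0, 86, True),
        ],
    )
    def test_strict_boundary_semantics(self, target_mae, target_std, n, expected):
        errors = _errors_with_mae_std(target_mae, target_std, n=2000)
        res = aami_check(errors, n_subjects=n)
        assert res.passed is expected


class TestBpCorrelation:
    def test_identity_prediction_has_unit_correlation(self, rng):
        sbp = rng.uniform(90, 180, 50)
        dbp = rng.uniform(60, 110, 50)
        r_s, r_d = bp_correlation(sbp, sbp, dbp, dbp)
        assert r_s == pytest.approx(1.0)
        assert r_d == pytest.approx(1.0)

    def test_shuffled_prediction_is_uncorrelated(self, rng):
        obs = rng.uniform(90, 180, 10_000)
        pred = rng.permutation(obs)
        r_s, _ = bp_correlation(pred, obs, pred, obs)
        assert abs(r_s) < 0.05


class TestEvaluateRun:
    def _waves(self, rng, n=120, t=200, n_subjects=90):
        waves = {}
        for i in range(n):
            base = 100 + 20 * np.sin(2 * np.pi * np.arange(t) / 50)
            waves[f"s{i % n_subjects:04d}_seg{i:04d}"] = base + rng.normal(0, 1, t)
        return waves

    def test_perfect_prediction_gives_zero_error_grade_a_aami_pass(self, rng):
        obs = self._waves(rng)
        report = evaluate_run(obs, obs, n_subjects=90)
        assert report.sbp_mae == 0.0 and report.sbp_rmse == 0.0
        assert report.bhs_sbp.grade == "A" and report.bhs_dbp.grade == "A"
        assert report.aami_sbp.passed and report.aami_dbp.passed
        assert report.r_sbp == pytest.approx(1.0)

    def test_constant_six_mmhg_offset_fails_bhs(self, rng):
        obs = self._waves(rng)
        pred = {k: v + 6.0 for k, v in obs.items()}
        report = evaluate_run(pred, obs, n_subjects=90)
        assert report.sbp_mae == pytest.approx(6.0)
        assert report.bhs_sbp.pct_le_5 == 0.0
        assert report.bhs_sbp.grade == "fail"

    def test_mismatched_ids_raise_pairing_error(self, rng):
        obs = self._waves(rng, n=5)
        pred = dict(list(obs.items())[:4])
        with pytest.raises(ValueError, match="do not match"):
            evaluate_run(pred, obs, n_subjects=5)

    def test_half_normal_errors_match_analytic_cdf(self, rng):
        scale = 3.0
        obs = self._waves(rng, n=100)
        offsets = np.abs(rng.normal(0, scale, 100))
        pred = {k: v + o for (k, v), o in zip(obs.items(), offsets)}
        report = evaluate_run(pred, obs, n_subjects=90)
        expected_pct = 100 * stats.halfnorm.cdf(5.0, scale=scale)
        assert report.bhs_sbp.pct_le_5 == pytest.approx(expected_pct, abs=5.0)

    def test_histogram_counts_sum_to_segment_count(self, rng):
        obs = self._waves(rng, n=60)
        pred = {k: v + rng.normal(0, 6) for k, v in obs.items()}
        report = evaluate_run(pred, obs, n_subjects=60)
        assert sum(report.abs_error_hist["sbp"].values()) == 60
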