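"""Tests for discrimination and calibration metrics."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest

from ntcpvalid import (
    CohortRecipe,
    NTCPError,
    PredictionSet,
    RunConfig,
    auc,
    auc_ci,
    brier_score,
    e_statistics,
    flexible_calibration_curve,
    generate_cohort,
    hosmer_lemeshow,
    predict_ntcp,
    report_to_json,
    sens_spec,
    validation_report,
)
from ntcpvalid.performance import CalibrationCurve, youden_threshold


def preds(p, y):
    p = np.asarray(p, dtype=float)
    return PredictionSet(np.zeros_like(p), p, np.asarray(y, dtype=int))


def auc_pair_oracle(p, y):
    """Exhaustive enumeration over all event/non-event pairs."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    pos, neg = p[y == 1], p[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc(preds([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])) == 1.0

    def test_all_ties(self):
        assert auc(preds([0.4] * 6, [0, 1, 0, 1, 0, 1])) == 0.5

    def test_hand_enumerated_example(self):
        assert auc(preds([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(NTCPError):
            auc(preds([0.2, 0.4], [1, 1]))

    def test_matches_exhaustive_pair_oracle_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            # coarse probabilities force ties
            p = rng.integers(0, 11, size=n) / 10.0
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert auc(preds(p, y)) == pytest.approx(auc_pair_oracle(p, y), abs=1e-12)

    def test_cross_check_against_sklearn(self, nipp, default_cohort):
        from sklearn.metrics import roc_auc_score

        pr = predict_ntcp(nipp, default_cohort)
        assert auc(pr) == pytest.approx(
            roc_auc_score(pr.outcome, pr.prob), abs=1e-12
        )


class TestAUCConfidenceInterval:
    def test_interval_contains_point_estimate(self, nipp, default_cohort):
        pr = predict_ntcp(nipp, default_cohort)
        lo, hi = auc_ci(pr)
        assert lo <= auc(pr) <= hi
        lo_b, hi_b = auc_ci(pr, method="bootstrap", n_resamples=200, seed=1)
        assert lo_b <= auc(pr) <= hi_b

    def test_width_scales_as_inverse_root_n(self):
        rng = np.random.default_rng(5)

        def mean_width(n, reps=40):
            widths = []
            while len(widths) < reps:
                s = rng.normal(0, 1, n)
                y = (rng.random(n) < expit(1.5 * s)).astype(int)
                if y.sum() in (0, n):
                    continue
                lo, hi = auc_ci(preds(expit(s), y))
                widths.append(hi - lo)
            return np.mean(widths)

        ratio = mean_width(400) / mean_width(100)
        assert ratio == pytest.approx(0.5, abs=0.12)

    def test_degenerate_all_ties_collapses_at_half(self):
        lo, hi = auc_ci(preds([0.3] * 20, [0, 1] * 10))
        assert lo == pytest.approx(0.5, abs=1e-12)
        assert hi == pytest.approx(0.5, abs=1e-12)


class TestSensSpec:
    @pytest.mark.parametrize(
        "p, y, threshold, expected",
        [
            ([0.4, 0.6], [0, 1], 0.5, (1.0, 1.0)),
            ([0.6, 0.4], [0, 1], 0.5, (0.0, 0.0)),
            ([0.2, 0.55, 0.45, 0.9], [0, 0, 1, 1], 0.5, (0.5, 0.5)),
        ],
    )
    def test_confusion_table_examples(self, p, y, threshold, expected):
        assert sens_spec(preds(p, y), threshold) == pytest.approx(expected)

    def test_youden_threshold_maximises_j(self):
        pr = preds([0.1, 0.3, 0.45, 0.6, 0.8], [0, 0, 1, 1, 1])
        t = youden_threshold(pr)
        sens, spec = sens_spec(pr, t)
        assert sens + spec - 1.0 == pytest.approx(1.0)


class TestBrier:
    def test_perfect_predictions(self):
        assert brier_score(preds([0.0, 1.0], [0, 1])) == 0.0

    def test_constant_half(self):
        assert brier_score(preds([0.5] * 8, [0, 1] * 4)) == pytest.approx(0.25)

    def test_hand_value(self):
        assert brier_score(preds([0.2, 0.8], [0, 1])) == pytest.approx(0.04, abs=1e-10)

    def test_decomposes_for_grouped_constant_predictions(self, rng):
        # Brier = sum_g w_g [(p_g - ybar_g)^2 + ybar_g (1 - ybar_g)]
        p_groups = [0.1, 0.3, 0.7]
        sizes = [20, 30, 50]
        p, y = [], []
        for pg, ng in zip(p_groups, sizes):
            yg = (rng.random(ng) < 0.4).astype(int)
            p.extend([pg] * ng)
            y.extend(yg)
        p, y = np.array(p), np.array(y)
        total = sum(sizes)
        decomposed = 0.0
        for pg, ng in zip(p_groups, sizes):
            yg = y[np.array(p) == pg]
            decomposed += ng / total * ((pg - yg.mean()) ** 2 + yg.mean() * (1 - yg.mean()))
        assert brier_score(preds(p, y)) == pytest.approx(decomposed, abs=1e-12)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_give_zero(self):
        p = [0.5] * 10 + [0.2] * 10
        y = [1] * 5 + [0] * 5 + [1] * 2 + [0] * 8
        x2, df, p_val = hosmer_lemeshow(preds(p, y), g=2, df=2)
        assert x2 == pytest.approx(0.0, abs=1e-10)
        assert p_val == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # group means 0.2 and 0.5, observed events 4 and 5 of 10:
        # X2 = (4-2)^2/2 + (6-8)^2/8 + 0 = 2.5
        p = [0.2] * 10 + [0.5] * 10
        y = [1] * 4 + [0] * 6 + [1] * 5 + [0] * 5
        x2, df, _ = hosmer_lemeshow(preds(p, y), g=2, df=2)
        assert x2 == pytest.approx(2.5, abs=1e-6)

    def test_fewer_observations_than_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(preds([0.5] * 5, [0, 1, 0, 1, 0]), g=10)

    def test_invariant_to_within_group_permutation(self, nipp, default_cohort, rng):
        pr = predict_ntcp(nipp, default_cohort)
        x2_ref, _, _ = hosmer_lemeshow(pr, g=10)
        # permute outcomes within each decile of predicted risk
        order = np.argsort(pr.prob, kind="stable")
        y_perm = pr.outcome.copy()
        for idx in np.array_split(order, 10):
            y_perm[idx] = y_perm[rng.permutation(idx)]
        x2_perm, _, _ = hosmer_lemeshow(
            PredictionSet(pr.linear, pr.prob, y_perm), g=10
        )
        assert x2_perm == pytest.approx(x2_ref, abs=1e-9)

    def test_p_value_approximately_uniform_under_the_null(self, nipp):
        # for externally fixed predictions (nothing estimated on the data)
        # the grouped statistic has ~g degrees of freedom; df = g - 2 is the
        # in-sample fitting convention
        cohort = generate_cohort(CohortRecipe(n=1000, seed=77))
        pr = predict_ntcp(nipp, cohort)
        rng = np.random.default_rng(78)
        pvals = []
        for _ in range(200):
            y = (rng.random(pr.n) < pr.prob).astype(int)
            _, _, p_val = hosmer_lemeshow(
                PredictionSet(pr.linear, pr.prob, y), g=10, df=10
            )
            pvals.append(p_val)
        assert kstest(pvals, "uniform").statistic < 0.1


class TestCalibrationCurve:
    def test_minimum_size_rule(self):
        with pytest.raises(NTCPError, match=">= 20"):
            flexible_calibration_curve(preds([0.2, 0.4, 0.6, 0.7, 0.9], [0, 0, 1, 1, 1]))

    def test_constant_predictions_rejected(self):
        with pytest.raises(NTCPError, match="constant"):
            flexible_calibration_curve(preds([0.4] * 30, [0, 1] * 15))

    def test_outcome_inverted_sample_lies_below_diagonal(self, rng):
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < 1.0 - p).astype(int)  # anti-calibrated
        curve = flexible_calibration_curve(preds(p, y))
        upper = curve.grid > 0.6
        assert np.all(curve.values[upper] < curve.grid[upper])

    def test_well_calibrated_curve_tracks_identity(self, nipp):
        cohort = generate_cohort(CohortRecipe(n=20_000, seed=55))
        pr = predict_ntcp(nipp, cohort)
        curve = flexible_calibration_curve(pr)
        lo, hi = np.quantile(pr.prob, [0.05, 0.95])
        central = (curve.grid >= lo) & (curve.grid <= hi)
        assert np.max(np.abs(curve.values[central] - curve.grid[central])) < 0.05


class TestEStatistics:
    def test_identity_curve_gives_zero(self):
        curve = CalibrationCurve(np.linspace(0, 1, 11), np.linspace(0, 1, 11))
        pr = preds([0.1, 0.4, 0.8], [0, 0, 1])
        assert e_statistics(curve, pr) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_hand_quantile_example(self):
        # distances 0.1, 0.2, 0.3 -> Emax 0.3, Eavg 0.2, E90 0.28
        grid = np.array([0.0, 1.0])
        curve = CalibrationCurve(grid, grid.copy())
        pr = preds([0.1, 0.2, 0.3], [0, 0, 1])
        shifted = CalibrationCurve(grid, np.array([-0.0, 0.0]))  # c(p) = 0
        emax, eavg, e90 = e_statistics(shifted, pr)
        assert emax == pytest.approx(0.3, abs=1e-9)
        assert eavg == pytest.approx(0.2, abs=1e-9)
        assert e90 == pytest.approx(0.28, abs=1e-9)

    def test_order_statistics_invariant(self, rng):
        grid = np.linspace(0, 1, 51)
        curve = CalibrationCurve(grid, np.clip(grid + rng.normal(0, 0.05, 51), 0, 1))
        pr = preds(rng.uniform(0, 1, 100), rng.integers(0, 2, 100))
        emax, eavg, e90 = e_statistics(curve, pr)
        assert eavg <= e90 <= emax

    def test_out_of_range_predictions_warn(self):
        curve = CalibrationCurve(np.array([0.2, 0.6]), np.array([0.2, 0.6]))
        with pytest.warns(UserWarning, match="endpoint"):
            e_statistics(curve, preds([0.1, 0.5, 0.9], [0, 1, 1]))


class TestValidationReport:
    def test_contains_all_levels_and_a_selection(self, nipp, default_cohort):
        report = validation_report(nipp, default_cohort)
        assert set(report["levels"]) == {
            "original", "intercept_update", "logistic_recalibration", "revision"
        }
        assert report["selected"] in report["levels"]
        for entry in report["levels"].values():
            assert {"discrimination", "calibration", "curve", "roc", "params"} <= set(entry)

    def test_byte_identical_reports_for_same_inputs(self, nipp, default_cohort):
        config = RunConfig(seed=5)
        a = report_to_json(validation_report(nipp, default_cohort, config))
        b = report_to_json(validation_report(nipp, default_cohort, config))
        assert a == b

    def test_youden_policy_reports_chosen_threshold(self, nipp, default_cohort):
        report = validation_report(nipp, default_cohort, RunConfig(threshold="youden"))
        disc = report["levels"]["original"]["discrimination"]
        assert 0.0 < disc["threshold"] < 1.0
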