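"""MR estimators, sensitivity statistics and the proteome screen."""

import numpy as np
import pytest
from scipy import stats

from protmr import (bonferroni_threshold, cochran_q, egger, ivw,
                    mode_estimators, run_proteome_mr, sim_mr_study,
                    wald_ratio, weighted_median)
from protmr.sumstats import InstrumentSet

from conftest import hset, row, table


class TestWald:
    def test_ratio_arithmetic(self):
        est = wald_ratio(0.5, 0.05, -0.5, 0.1)
        assert est.beta == pytest.approx(-1.0)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert est.beta == 0.0 and est.or_ == pytest.approx(1.0)

    def test_null_instrument_refused(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.1, 0.1)

    def test_first_order_se_vs_monte_carlo(self, rng):
        # strong instrument (|beta_exp|/se_exp = 25): the delta-method SE
        # should match the empirical SD of the ratio distribution
        be, se_e, bo, so = 0.5, 0.02, -0.3, 0.1
        est = wald_ratio(be, se_e, bo, so)
        draws = (bo + so * rng.standard_normal(100_000)) / \
                (be + se_e * rng.standard_normal(100_000))
        assert est.se == pytest.approx(np.std(draws), rel=0.15)

    def test_or_ci_consistency(self):
        est = wald_ratio(0.5, 0.05, -0.5, 0.1)
        assert est.or_ == pytest.approx(np.exp(est.beta), abs=1e-15)
        assert est.ci_low == pytest.approx(
            np.exp(est.beta - stats.norm.ppf(0.975) * est.se), abs=1e-12)


class TestIVW:
    def test_identical_ratios_exact(self):
        h = hset([0.2, 0.4], 0.01, [0.06, 0.12], 0.05)
        assert ivw(h).beta == pytest.approx(0.3, abs=1e-12)

    def test_equal_weight_mean(self):
        h = hset([0.2, 0.2], 0.01, [0.02, 0.06], 0.05)
        assert ivw(h).beta == pytest.approx(0.2, abs=1e-12)

    def test_refuses_single_instrument(self):
        with pytest.raises(ValueError):
            ivw(hset([0.2], 0.01, [0.06], 0.05))

    def test_equals_wald_for_identical_instruments(self):
        h = hset([0.3, 0.3], 0.01, [0.09, 0.09], 0.05)
        w = wald_ratio(0.3, 0.01, 0.09, 0.05)
        assert ivw(h).beta == pytest.approx(w.beta, abs=1e-12)

    def test_invariant_to_order_and_joint_sign_flip(self, rng):
        be = rng.uniform(0.1, 0.3, 8)
        bo = 0.4 * be + 0.01 * rng.standard_normal(8)
        h = hset(be, 0.01, bo, 0.05)
        perm = rng.permutation(8)
        h_perm = hset(be[perm], 0.01, bo[perm], 0.05)
        flip = np.ones(8)
        flip[2] = -1
        h_flip = hset(be * flip, 0.01, bo * flip, 0.05)
        assert ivw(h).beta == pytest.approx(ivw(h_perm).beta, abs=1e-12)
        assert ivw(h).beta == pytest.approx(ivw(h_flip).beta, abs=1e-12)

    def test_parameter_recovery_small(self, rng):
        # quick bias check; the full-scale recovery experiment lives in the
        # acceptance suite
        theta = np.log(0.35)
        errs = []
        for rep in range(100):
            exps, out, _ = sim_mr_study(1, 1, 30, effect_size=theta,
                                        seed=1000 + rep)
            from protmr import harmonize
            h = harmonize(exps["P000"].table, out)
            errs.append(ivw(h).beta - theta)
        assert abs(np.mean(errs)) < 0.03


class TestEgger:
    def test_collinear_through_origin_zero_intercept(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset(be, 0.01, 0.5 * be, 0.05)
        est, (intercept, se_i, p_i) = egger(h)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_refuses_below_three(self):
        with pytest.raises(ValueError):
            egger(hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.05))

    def test_directional_pleiotropy_recovered(self, rng):
        # constant +0.1 added to every outcome beta shifts the intercept
        ints = []
        for rep in range(200):
            exps, out, _ = sim_mr_study(1, 1, 30, effect_size=0.3,
                                        pleiotropy="directional",
                                        pleiotropy_scale=0.1,
                                        seed=2000 + rep)
            from protmr import harmonize
            h = harmonize(exps["P000"].table, out)
            ints.append(egger(h)[1][0])
        assert np.mean(ints) == pytest.approx(0.1, abs=0.03)


class TestWeightedMedian:
    def test_outlier_robust(self):
        h = hset(np.ones(5) * 0.2, 0.01,
                 np.array([0.2, 0.2, 0.2, 0.2, 2.0]), 0.05)
        assert weighted_median(h, nboot=100).beta == pytest.approx(1.0,
                                                                   abs=0.01)

    def test_interpolation_midpoint(self):
        h = hset([0.2, 0.2], 0.01, [0.0, 0.4], 0.05)
        assert weighted_median(h, nboot=100).beta == pytest.approx(1.0)

    def test_bootstrap_se_matches_simulation_sd(self, rng):
        # oracle: SD of the point estimate across freshly simulated
        # datasets with the same generating parameters
        k = 20
        be_true = rng.uniform(0.15, 0.3, k)
        se_e, se_o = 0.01, 0.05
        bo_true = 0.4 * be_true
        points = []
        for _ in range(2000):
            be = be_true + se_e * rng.standard_normal(k)
            bo = bo_true + se_o * rng.standard_normal(k)
            from protmr.mr import _weighted_median_of
            points.append(_weighted_median_of(bo / be, be ** 2 / se_o ** 2))
        sim_sd = np.std(points, ddof=1)
        h = hset(be_true + se_e * rng.standard_normal(k), se_e,
                 bo_true + se_o * rng.standard_normal(k), se_o)
        est = weighted_median(h, nboot=2000, seed=5)
        assert est.se == pytest.approx(sim_sd, rel=0.15)

    def test_small_nboot_warns(self):
        h = hset([0.2, 0.3], 0.01, [0.06, 0.09], 0.05)
        with pytest.warns(UserWarning, match="nboot"):
            weighted_median(h, nboot=50)


class TestModes:
    def test_degenerate_identical_ratios(self):
        be = np.array([0.1, 0.2, 0.4])
        h = hset(be, 0.01, 0.4 * be, 0.05)
        wm, sm = mode_estimators(h, nboot=100)
        assert wm.beta == pytest.approx(0.4) and wm.se == 0.0
        assert sm.beta == pytest.approx(0.4)

    def test_majority_cluster_found(self, rng):
        ratios = np.array([0.18, 0.2, 0.22, 0.19, 0.21, 0.2, 0.23,
                           1.0, 1.05, 0.95])
        be = np.full(10, 0.2)
        h = hset(be, 0.01, ratios * be, 0.05)
        wm, sm = mode_estimators(h, nboot=100, seed=1)
        assert 0.1 <= wm.beta <= 0.3
        assert 0.1 <= sm.beta <= 0.3

    def test_weighted_equals_simple_under_equal_weights(self):
        be = np.full(6, 0.25)
        bo = np.array([0.05, 0.06, 0.07, 0.05, 0.2, 0.06])
        h = hset(be, 0.01, bo, 0.05)
        wm, sm = mode_estimators(h, nboot=100, seed=2)
        assert wm.beta == pytest.approx(sm.beta, abs=1e-12)


class TestCochranQ:
    def test_identical_ratios(self):
        h = hset([0.2, 0.4], 0.01, [0.06, 0.12], 0.05)
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-18) and p == 1.0 and df == 1

    def test_two_point_closed_form(self):
        # equal weights w, ratios 0 and 2 -> Q = 2w
        be, so = 0.2, 0.05
        h = hset([be, be], 0.01, [0.0, 2 * be], so)
        q, df, _ = cochran_q(h)
        w = be ** 2 / so ** 2
        assert q == pytest.approx(2 * w)

    def test_homogeneous_calibration(self, rng):
        qs = []
        for _ in range(400):
            be = rng.uniform(0.15, 0.3, 10)
            bo = 0.3 * be + 0.05 * rng.standard_normal(10)
            q, df, _ = cochran_q(hset(be, 0.005, bo, 0.05))
            qs.append(q / df)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.1)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 1972, 2.54e-5),
        (0.05, 1, 0.05),
        (0.05, 20, 2.5e-3),
    ])
    def test_threshold(self, alpha, m, expected):
        got = bonferroni_threshold(alpha, m)
        assert float(f"{got:.3g}") == pytest.approx(expected)


class TestProteomeScreen:
    def test_single_instrument_dispatches_wald(self):
        exps, out, _ = sim_mr_study(1, 0, 1, seed=3)
        scr = run_proteome_mr(exps, out, methods="primary")
        assert scr.results["P000"].primary.method == "wald"

    def test_zero_instrument_protein_listed_untested(self):
        exps, out, _ = sim_mr_study(2, 0, 3, seed=4)
        empty = InstrumentSet("PXXX", table([row(pval=0.9)], "PXXX"), [],
                             "empty")
        empty.table.df = empty.table.df.iloc[:0]
        exps["PXXX"] = empty
        scr = run_proteome_mr(exps, out, methods="primary")
        assert scr.results["PXXX"].status == "untested"
        assert scr.n_tested == 2

    def test_threshold_uses_tested_count(self):
        exps, out, _ = sim_mr_study(10, 0, 3, seed=5)
        scr = run_proteome_mr(exps, out, alpha=0.05, methods="primary")
        assert scr.threshold == pytest.approx(0.05 / 10)

    def test_planted_effects_flagged_without_false_positives(self):
        exps, out, truth = sim_mr_study(40, 5, 10, effect_size=np.log(0.35),
                                        seed=6)
        scr = run_proteome_mr(exps, out, methods="primary")
        flagged = set(scr.significant_proteins)
        causal = {p for p, v in truth.causal_effects.items() if v != 0}
        # every planted effect found; false flags bounded by the Bonferroni
        # family-wise guarantee (>= 2 has probability ~0.1%)
        assert causal <= flagged
        assert len(flagged - causal) <= 1

    def test_all_methods_attached_when_permitted(self):
        exps, out, _ = sim_mr_study(1, 1, 10, seed=7)
        scr = run_proteome_mr(exps, out, methods="all", nboot=200)
        ests = scr.results["P000"].estimates
        assert {"ivw", "egger", "weighted_median", "weighted_mode",
                "simple_mode"} <= set(ests)
        sens = scr.results["P000"].sensitivity
        assert sens.q_df == 9 and 0 < sens.q_pval <= 1
        assert sens.egger_intercept_pval is not None
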