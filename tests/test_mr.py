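"""Wald-ratio MR estimates, delta-method standard errors, instrument
diagnostics, subgroup tests and the analysis battery, checked against
hand evaluations, Monte-Carlo oracles and published worked examples."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from bittermr import (
    AnalysisPlan,
    AssociationResult,
    GeneticInstrument,
    bonferroni_threshold,
    causal_or,
    difference_test,
    instrument_F,
    mr_power,
    run_mr_battery,
    se_from_ci,
    subgroup_difference_test,
    wald_ratio,
)
from bittermr.mr import mr_table, sex_difference_tests
from bittermr.reported import reported_instruments


def _instrument(beta=0.264, se=0.048, stim="caffeine") -> GeneticInstrument:
    return GeneticInstrument("rs2597979", "G", stim, beta, se, 0.02, 1757)


def _assoc(beta, se, model="linear", **kw) -> AssociationResult:
    return AssociationResult("rs2597979", "coffee", beta, se, 438_870, model, **kw)


class TestWaldRatio:
    def test_point_estimate_is_ratio(self):
        res = wald_ratio(_assoc(0.039, 0.0059), _instrument())
        assert res.estimate == pytest.approx(0.039 / 0.264)

    def test_null_numerator_gives_null_estimate(self):
        res = wald_ratio(_assoc(0.0, 0.01), _instrument())
        assert res.estimate == 0.0
        assert res.p == 1.0

    def test_first_order_se_scales_numerator(self):
        res = wald_ratio(_assoc(0.039, 0.0059), _instrument(), se_mode="first_order")
        assert res.se == pytest.approx(0.0059 / 0.264)

    def test_full_delta_formula(self):
        b_bev, se_bev, b, se_b = 0.039, 0.0059, 0.264, 0.048
        res = wald_ratio(_assoc(b_bev, se_bev), _instrument(se=se_b))
        manual = math.sqrt(se_bev**2 / b**2 + b_bev**2 * se_b**2 / b**4)
        assert res.se == pytest.approx(manual)

    def test_first_order_scales_published_ci_bounds(self):
        assoc = _assoc(0.039, 0.0059, ci_low=0.027, ci_high=0.050)
        res = wald_ratio(assoc, _instrument(), se_mode="first_order")
        assert res.ci_low == pytest.approx(0.027 / 0.264)
        assert res.ci_high == pytest.approx(0.050 / 0.264)

    def test_se_modes_converge_as_instrument_se_vanishes(self):
        assoc = _assoc(0.039, 0.0059)
        first = wald_ratio(assoc, _instrument(), se_mode="first_order")
        gaps = [
            wald_ratio(assoc, _instrument(se=se_b)).se - first.se
            for se_b in (0.05, 0.02, 0.001, 1e-6)
        ]
        assert all(g > 0 for g in gaps[:-1])  # full delta is always wider
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] == pytest.approx(0.0, abs=1e-9)

    def test_scale_equivariance(self):
        """Multiplying the outcome by c multiplies estimate and SE by c."""
        res1 = wald_ratio(_assoc(0.039, 0.0059), _instrument())
        res2 = wald_ratio(_assoc(0.39, 0.059), _instrument())
        assert res2.estimate == pytest.approx(10 * res1.estimate)
        assert res2.se == pytest.approx(10 * res1.se)
        assert res2.p == pytest.approx(res1.p)

    def test_requires_linear_model(self):
        with pytest.raises(ValueError, match="linear"):
            wald_ratio(_assoc(0.05, 0.01, model="logistic"), _instrument())

    def test_delta_se_matches_monte_carlo(self):
        """Full-delta SE within 5% of the empirical ratio SD over 10,000
        parametric replicates when the instrument z exceeds 10."""
        rng = np.random.default_rng(7)
        b_bev, se_bev = -0.0203, 0.0045
        b_bit, se_bit = 0.965, 0.0804  # z = 12
        ratios = rng.normal(b_bev, se_bev, 10_000) / rng.normal(b_bit, se_bit, 10_000)
        res = wald_ratio(
            _assoc(b_bev, se_bev),
            GeneticInstrument("rs1726866", "G", "prop", b_bit, se_bit, 0.46, 1757),
        )
        assert res.se == pytest.approx(float(np.std(ratios, ddof=1)), rel=0.05)


class TestCausalOR:
    def test_null_log_or_gives_or_one(self):
        res = causal_or(_assoc(0.0, 0.01, model="logistic"), _instrument())
        assert res.estimate == 1.0

    def test_round_trips_published_heavy_coffee_or(self):
        """log OR_drinkstatus = ln(1.207)*0.264 divided back by 0.264 and
        exponentiated recovers the published causal OR 1.207."""
        log_or = math.log(1.207) * 0.264
        res = causal_or(_assoc(log_or, 0.01, model="logistic"), _instrument())
        assert res.estimate == pytest.approx(1.207, abs=1e-9)

    def test_published_or_ci_symmetric_on_log_scale(self):
        lo, mid, hi = 1.126, 1.207, 1.294
        low_half = math.log(mid) - math.log(lo)
        high_half = math.log(hi) - math.log(mid)
        assert abs(low_half - high_half) < 0.001

    def test_or_equals_exp_of_log_scale_ratio(self):
        assoc = _assoc(0.05, 0.012, model="linear_approx_logOR")
        inst = _instrument()
        res = causal_or(assoc, inst)
        log_res = wald_ratio(
            AssociationResult(assoc.snp, assoc.phenotype, assoc.beta, assoc.se,
                              assoc.n, "linear"),
            inst,
        )
        assert res.estimate == pytest.approx(math.exp(log_res.estimate))
        assert res.ci_low == pytest.approx(math.exp(log_res.ci_low))
        assert res.se == pytest.approx(log_res.se)

    def test_requires_log_or_model(self):
        with pytest.raises(ValueError, match="logistic"):
            causal_or(_assoc(0.05, 0.01, model="linear"), _instrument())


class TestInstrumentF:
    @pytest.mark.parametrize("r2,n,expected", [(0.0, 100, 0.0), (0.5, 4, 2.0)])
    def test_hand_values(self, r2, n, expected):
        assert instrument_F(r2, n) == pytest.approx(expected)

    def test_weak_instrument_threshold_inversion(self):
        # R^2 giving F = 10 at n = 1757: R^2 = 10 / (n - 2 + 10)
        r2 = 10 / (1757 - 2 + 10)
        assert instrument_F(r2, 1757) == pytest.approx(10.0)
        assert r2 == pytest.approx(0.00567, abs=5e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            instrument_F(1.2, 100)
        with pytest.raises(ValueError):
            instrument_F(0.1, 2)

    def test_reported_instruments_are_strong(self):
        for inst in reported_instruments():
            assert inst.f() > 10


class TestPower:
    def test_size_under_the_null(self):
        for alpha in (0.05, 0.00556):
            assert mr_power(400_000, 0.02, 0.0, alpha) == pytest.approx(alpha)

    def test_monotone_in_n_r2_and_effect(self):
        base = mr_power(10_000, 0.02, 0.05)
        assert mr_power(40_000, 0.02, 0.05) > base
        assert mr_power(10_000, 0.08, 0.05) > base
        assert mr_power(10_000, 0.02, 0.10) > base
        assert mr_power(10_000, 0.02, -0.10) > base  # two-sided in |effect|

    def test_detected_effects_have_high_power_at_biobank_scale(self):
        # largest detected coffee effect, standardized: 0.146/2.1 = 0.0695 SD;
        # smallest: 0.021/2.1 = 0.01 SD with the strongest instrument
        assert mr_power(438_870, 0.02, 0.146 / 2.1, 0.00556) > 0.99
        assert mr_power(438_870, 0.46, 0.021 / 2.1, 0.00556) > 0.9

    def test_matches_simulation_oracle_at_reduced_n(self):
        """Closed-form power vs the rejection rate of the Wald z-test over
        simulated instrument-outcome draws (n = 4000, R^2 = 0.02,
        standardized effect 0.3)."""
        n, r2, effect, alpha = 4000, 0.02, 0.3, 0.05
        rng = np.random.default_rng(13)
        reps = 4000
        se = 1.0 / math.sqrt(n * r2)  # SE of the standardized IV estimate
        est = rng.normal(effect, se, reps)
        rej = np.mean(np.abs(est / se) > norm.ppf(1 - alpha / 2))
        assert mr_power(n, r2, effect, alpha) == pytest.approx(float(rej), abs=0.03)


class TestSeFromCI:
    def test_unit_normal(self):
        assert se_from_ci(-1.96, 1.96) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.103, 0.189, 0.0219), (-0.341, -0.182, 0.0406)],
    )
    def test_published_interval_widths(self, lo, hi, expected):
        assert se_from_ci(lo, hi) == pytest.approx(expected, abs=5e-4)

    def test_round_trip_with_wald_interval(self):
        beta, se = 0.42, 0.107
        z = norm.ppf(0.975)
        assert se_from_ci(beta - z * se, beta + z * se) == pytest.approx(se)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            se_from_ci(1.0, 0.5)
        with pytest.raises(ValueError):
            se_from_ci(0.0, 1.0, level=1.5)


class TestSubgroupDifference:
    def test_hand_evaluation(self):
        z, p = difference_test(1.0, 0.5, 0.0, 0.5)
        assert z == pytest.approx(math.sqrt(2), abs=1e-6)
        assert p == pytest.approx(0.157, abs=1e-3)

    def test_identical_estimates_give_p_one(self):
        z, p = difference_test(0.3, 0.1, 0.3, 0.2)
        assert z == 0.0
        assert p == 1.0

    def test_published_sex_difference_p(self):
        """Female vs male caffeine-tea estimates reconstructed from their
        CIs give the published difference p = 0.007."""
        se_f = se_from_ci(-0.341, -0.182)
        se_m = se_from_ci(-0.184, 0.004)
        _, p = difference_test(-0.261, se_f, -0.091, se_m)
        assert p == pytest.approx(0.007, abs=5e-4)

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            difference_test(1.0, 0.0, 0.0, 0.5)

    def test_requires_common_scale(self):
        lin = wald_ratio(_assoc(0.039, 0.0059), _instrument())
        odds = causal_or(_assoc(0.05, 0.012, model="logistic"), _instrument())
        with pytest.raises(ValueError, match="scale"):
            subgroup_difference_test(lin, odds)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 9, 0.00556), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, abs=5e-6)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


@pytest.fixture(scope="module")
def battery(harmonized_small, sample1):
    from bittermr import fit_taste_instruments

    instruments = fit_taste_instruments(sample1)
    return run_mr_battery(harmonized_small, instruments)


class TestBattery:
    def test_main_grid_has_nine_cells(self, battery):
        mr_results, _ = battery
        main = [r for r in mr_results if r.analysis == "main"]
        assert len(main) == 9
        assert {(r.stimulus, r.outcome) for r in main} == {
            (s, o)
            for s in ("prop", "quinine", "caffeine")
            for o in ("coffee", "tea", "alcohol_freq_month")
        }

    def test_conditional_cells(self, battery):
        mr_results, _ = battery
        cond = [r for r in mr_results if r.analysis == "conditional"]
        assert len(cond) == 6  # 3 stimuli x 2 conditional outcomes

    def test_by_sex_cells_and_difference_table(self, battery):
        mr_results, _ = battery
        by_sex = [r for r in mr_results if r.analysis == "by_sex"]
        assert len(by_sex) == 18  # 3 stimuli x 3 outcomes x 2 sexes
        diffs = sex_difference_tests(mr_results)
        assert len(diffs) == 9
        assert ((diffs["p"] > 0) & (diffs["p"] <= 1)).all()

    def test_main_results_flagged_against_bonferroni(self, battery):
        mr_results, _ = battery
        thr = bonferroni_threshold(0.05, 9)
        for r in mr_results:
            if r.analysis == "main":
                assert r.significant == (r.p < thr)

    def test_plan_with_no_extras_is_main_only(self, harmonized_small, sample1):
        from bittermr import fit_taste_instruments

        plan = AnalysisPlan(
            binary_contrasts=False, conditional_pairs=(), strata=(), by_sex=False
        )
        mr_results, _ = run_mr_battery(
            harmonized_small, fit_taste_instruments(sample1), plan
        )
        assert {r.analysis for r in mr_results} == {"main"}
        assert len(mr_results) == 9

    def test_empty_stratum_skipped_with_warning(self, harmonized_small, sample1):
        from bittermr import StratumSpec, fit_taste_instruments

        plan = AnalysisPlan(
            binary_contrasts=False,
            conditional_pairs=(),
            by_sex=False,
            strata=(StratumSpec("impossible", "coffee", "coffee > 1000"),),
        )
        with pytest.warns(UserWarning, match="skipping"):
            mr_results, _ = run_mr_battery(
                harmonized_small, fit_taste_instruments(sample1), plan
            )
        assert all(r.analysis == "main" for r in mr_results)

    def test_table_layout(self, battery):
        mr_results, _ = battery
        df = mr_table(mr_results)
        assert {"analysis", "stimulus", "outcome", "estimate", "ci_low", "ci_high", "p"} <= set(df.columns)
        assert len(df) == len(mr_results)
        assert (df["ci_low"] <= df["estimate"]).all()
        assert (df["estimate"] <= df["ci_high"]).all()
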