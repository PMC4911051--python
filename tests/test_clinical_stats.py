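import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnbctype.clinical_stats import (binomial_ci, contingency_test,
                                     cox_continuous, km_fit,
                                     odds_ratio_vs_cohort,
                                     subtype_outcome_report)
from tnbctype.synthetic_data import CohortConfig, generate_cohort

# grade (1/2/3) x subtype counts as published
GRADE_TABLE = [[0, 14, 98], [2, 12, 56], [1, 23, 60], [5, 14, 31]]


class TestContingency:
    def test_grade_by_subtype_chi_square(self):
        res = contingency_test(GRADE_TABLE, method="chisq")
        assert 2.9e-4 <= res.p_value <= 3.1e-4
        assert res.df == 6

    def test_chisq_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 40, size=(4, 3)).astype(float)
            res = contingency_test(t, method="chisq")
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
            oracle = ((t - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(oracle, rel=1e-12)

    def test_proportional_rows_give_zero_statistic(self):
        res = contingency_test([[10, 20, 30], [20, 40, 60]], method="chisq")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_margin_fixed_enumeration(self):
        a = np.array([[3, 1], [1, 3]])
        res = contingency_test(a, method="fisher")
        # enumerate all tables with the observed margins
        r1, r2 = a.sum(axis=1)
        c1 = a.sum(axis=0)[0]
        n = a.sum()
        def prob(x):
            return (math.comb(r1, x) * math.comb(r2, c1 - x)
                    / math.comb(n, c1))
        p_obs = prob(a[0, 0])
        oracle = sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                     if prob(x) <= p_obs + 1e-12)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_fisher_equals_hypergeometric_enumeration_many_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum() > 40 or \
               (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
                continue
            res = contingency_test(t, method="fisher")
            r1, r2 = t.sum(axis=1)
            c1 = t.sum(axis=0)[0]
            n = t.sum()
            lo, hi = max(0, c1 - r2), min(r1, c1)
            probs = {x: stats.hypergeom.pmf(x, n, r1, c1)
                     for x in range(lo, hi + 1)}
            p_obs = probs[t[0, 0]]
            oracle = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
            assert res.p_value == pytest.approx(oracle, rel=1e-6)

    def test_auto_selects_fisher_for_sparse_2x2(self):
        assert contingency_test([[1, 4], [5, 2]], method="auto").method == "fisher"
        assert contingency_test([[20, 30], [25, 25]],
                                method="auto").method == "chisq"

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = contingency_test([[5, 0, 5], [3, 0, 7]], method="chisq")
        assert res.table.shape == (2, 2)


class TestOddsRatio:
    def test_equal_rates_give_or_one(self):
        out = odds_ratio_vs_cohort({"n_pcr": 30, "n_total": 100},
                                   {"n_pcr": 90, "n_total": 300})
        assert out.or_point == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        out = odds_ratio_vs_cohort({"n_pcr": 45, "n_total": 110},
                                   {"n_pcr": 101, "n_total": 306})
        oracle = (45 / 65) / (101 / 205)
        assert out.or_point == pytest.approx(oracle)
        assert round(out.or_point, 3) == 1.405
        assert out.ci_low <= out.or_point <= out.ci_high

    def test_zero_cell_continuity_correction(self):
        out = odds_ratio_vs_cohort({"n_pcr": 0, "n_total": 20},
                                   {"n_pcr": 100, "n_total": 300})
        assert np.isfinite(out.or_point) and out.or_point > 0

    def test_group_vs_itself_is_exactly_one(self):
        out = odds_ratio_vs_cohort({"n_pcr": 37, "n_total": 80},
                                   {"n_pcr": 37, "n_total": 80})
        assert out.or_point == pytest.approx(1.0)

    def test_monotone_in_group_successes(self):
        cohort = {"n_pcr": 100, "n_total": 300}
        ors = [odds_ratio_vs_cohort({"n_pcr": k, "n_total": 50}, cohort).or_point
               for k in range(1, 50)]
        assert np.all(np.diff(ors) > 0)


class TestBinomialCI:
    def test_clopper_pearson_boundary_cases(self):
        lo, _ = binomial_ci(0, 10, method="clopper_pearson")
        _, hi = binomial_ci(10, 10, method="clopper_pearson")
        assert lo == 0.0 and hi == 100.0

    def test_wilson_matches_closed_form(self):
        k, n, z = 45, 110, stats.norm.ppf(0.975)
        p = k / n
        denom = 1 + z ** 2 / n
        center = (p + z ** 2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
        lo, hi = binomial_ci(k, n, method="wilson")
        assert lo == pytest.approx(100 * (center - half), rel=1e-9)
        assert hi == pytest.approx(100 * (center + half), rel=1e-9)

    def test_wilson_coverage_near_nominal(self):
        # 2000 simulated rates at p = 0.3, n = 110
        rng = np.random.default_rng(5)
        ks = rng.binomial(110, 0.3, size=2000)
        covered = 0
        for k in ks:
            lo, hi = binomial_ci(int(k), 110, method="wilson")
            covered += lo <= 30.0 <= hi
        assert 0.93 <= covered / 2000 <= 0.97


class TestSurvival:
    def test_product_limit_hand_example(self):
        out = km_fit([1, 2, 3], [1, 1, 1], logrank=False)
        curve = out["curves"][0].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)
        assert out["medians"][0] == pytest.approx(2.0)

    def test_no_events_curve_stays_at_one(self):
        out = km_fit([5, 6, 7], [0, 0, 0], logrank=False)
        assert (out["curves"][0]["survival"] == 1.0).all()
        assert np.isnan(out["medians"][0])

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(2.0, size=60)
        out = km_fit(t, np.ones(60, dtype=int), logrank=False)
        curve = out["curves"][0]
        for time, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_identical_groups_logrank_null(self):
        t = np.array([1, 2, 3, 4, 5.0] * 2)
        e = np.ones(10, dtype=int)
        g = np.array([0] * 5 + [1] * 5)
        out = km_fit(t, e, g)
        assert out["logrank_stat"] == pytest.approx(0.0, abs=1e-9)
        assert out["logrank_p"] == pytest.approx(1.0)

    def test_single_group_logrank_is_an_error(self):
        with pytest.raises(ValueError, match="two groups"):
            km_fit([1, 2, 3], [1, 1, 1], [0, 0, 0])


class TestCox:
    @staticmethod
    def _simulate(beta, n, rng):
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-beta * x))
        c = rng.uniform(0, np.quantile(t, 0.9), size=n)
        return x, np.minimum(t, c), (t <= c).astype(int)

    def test_recovers_generating_coefficient(self):
        rng = np.random.default_rng(13)
        x, t, e = self._simulate(0.5, 500, rng)
        out = cox_continuous(x, t, e)
        assert abs(out["beta"] - 0.5) <= 0.15
        assert out["lrt_p"] < 1e-6

    def test_matches_lifelines_estimate(self):
        import lifelines
        rng = np.random.default_rng(14)
        x, t, e = self._simulate(0.7, 300, rng)
        ours = cox_continuous(x, t, e)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert ours["beta"] == pytest.approx(float(cph.params_["x"]), abs=1e-3)

    def test_null_rejection_rate_near_alpha(self):
        # permuted covariate: LRT should reject ~5% of the time
        rejections = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            x, t, e = self._simulate(0.0, 150, rng)
            out = cox_continuous(x, t, e)
            rejections += out["lrt_p"] < 0.05
        assert 0.02 <= rejections / 200 <= 0.08

    def test_reparameterization(self):
        rng = np.random.default_rng(15)
        x, t, e = self._simulate(0.5, 400, rng)
        a = cox_continuous(x, t, e)
        b = cox_continuous(3.0 * x, t, e)
        assert b["beta"] == pytest.approx(a["beta"] / 3.0, rel=1e-4)
        # hazard ratio at +1 SD of the covariate is scale-invariant
        assert np.exp(b["beta"] * np.std(3 * x)) == pytest.approx(
            np.exp(a["beta"] * np.std(x)), rel=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_continuous(np.ones(30), np.arange(1, 31.0), np.ones(30))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_continuous(np.arange(12.0), np.arange(1, 13.0),
                           [1] * 5 + [0] * 7)


class TestOutcomeReport:
    def test_configured_pcr_rates_recovered_within_binomial_envelope(self):
        sim = generate_cohort(CohortConfig(n_samples=5000, seed=17))
        clin = sim["clinical"]
        report = subtype_outcome_report(clin, by="subtype")
        tab = report["pcr_table"].set_index("group")
        cfg_rates = sim["config"].pcr_rates
        for sub, rate in cfg_rates.items():
            n = tab.loc[sub, "n"]
            half = 3.0 * np.sqrt(rate * (1 - rate) / n)
            assert abs(tab.loc[sub, "pcr_rate_pct"] / 100 - rate) <= half, sub

    def test_null_rates_give_or_near_one(self):
        sim = generate_cohort(CohortConfig(
            n_samples=2000, seed=18,
            pcr_rates={"BL1": 0.3, "BL2": 0.3, "M": 0.3, "LAR": 0.3}))
        report = subtype_outcome_report(sim["clinical"], by="subtype")
        tab = report["pcr_table"]
        assert np.all(np.abs(tab["or"] - 1.0) < 0.4)

    def test_single_subtype_reduces_to_self_comparison(self):
        clin = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(40)],
            "subtype": ["BL1"] * 40,
            "pcr": ([1] * 15 + [0] * 25),
        })
        report = subtype_outcome_report(clin, by="subtype")
        assert report["pcr_table"]["or"].iloc[0] == pytest.approx(1.0)

    def test_small_groups_excluded_with_warning(self):
        clin = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(23)],
            "subtype": ["BL1"] * 20 + ["LAR"] * 3,
            "pcr": [1, 0] * 10 + [1, 0, 0],
        })
        with pytest.warns(UserWarning, match="LAR"):
            report = subtype_outcome_report(clin, by="subtype")
        tab = report["pcr_table"].set_index("group")
        assert np.isnan(tab.loc["LAR", "or"])

    def test_survival_section_reports_each_vs_rest(self):
        sim = generate_cohort(CohortConfig(n_samples=800, seed=19))
        report = subtype_outcome_report(sim["clinical"], by="subtype")
        assert "os" in report["survival"]
        evr = report["survival"]["os"]["each_vs_rest"]
        assert set(evr) == {"BL1", "BL2", "M", "LAR"}
        for entry in evr.values():
            assert 0 <= entry["p"] <= 1
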