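"""Selective intervals, Bonferroni correction, and the stacked bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slcma import (
    EffectEstimate,
    SimulationParams,
    bonferroni_refit,
    percentile_interval,
    selective_inference,
    simulate_cohort,
    stacked_bootstrap,
)
from slcma.inference import _invert_pivot, _truncated_normal_pivot
from slcma.path import lasso_path_logistic


class TestTruncatedNormalMachinery:
    def test_pivot_matches_scipy_truncnorm(self):
        for mu, sigma, a, b, t in [(0.5, 1.2, -1.0, 2.0, 1.0), (0.0, 0.7, 0.2, np.inf, 0.9)]:
            got = _truncated_normal_pivot(t, mu, sigma, a, b)
            want = stats.truncnorm.cdf(t, (a - mu) / sigma, (b - mu) / sigma, loc=mu, scale=sigma)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invert_pivot_round_trips(self):
        t, sigma, a, b = 1.3, 0.8, 0.5, 4.0
        mu = _invert_pivot(t, sigma, a, b, 0.3)
        assert _truncated_normal_pivot(t, mu, sigma, a, b) == pytest.approx(0.3, abs=1e-6)

    def test_untruncated_interval_is_wald(self):
        t, sigma = 0.9, 0.4
        lo = _invert_pivot(t, sigma, -np.inf, np.inf, 0.975)
        hi = _invert_pivot(t, sigma, -np.inf, np.inf, 0.025)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(t - z * sigma, abs=1e-6)
        assert hi == pytest.approx(t + z * sigma, abs=1e-6)


class TestSelectiveInference:
    def _fit_path(self, rng, n=1500, beta=(0.6, 0.0, 0.0)):
        X = rng.standard_normal((n, len(beta)))
        eta = -1.2 + X @ np.asarray(beta)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return lasso_path_logistic(X, y)

    def test_no_conditioning_equals_working_wald(self, rng):
        """With the selection event switched off, the selective interval is
        the naive Wald interval of the working model to 1e-6."""
        path = self._fit_path(rng)
        sel = selective_inference(path, k=1, condition=False)[0]
        z = stats.norm.ppf(0.975)
        lo = np.exp(sel.log_or - z * sel.se)
        hi = np.exp(sel.log_or + z * sel.se)
        assert sel.ci_low == pytest.approx(lo, abs=1e-6)
        assert sel.ci_high == pytest.approx(hi, abs=1e-6)
        assert sel.method == "naive_wald"

    def test_selective_interval_never_shorter_than_naive(self, rng):
        path = self._fit_path(rng, beta=(0.4, 0.1, 0.0))
        sel = selective_inference(path, k=1)[0]
        nai = selective_inference(path, k=1, condition=False)[0]
        len_sel = np.log(sel.ci_high) - np.log(sel.ci_low)
        len_nai = np.log(nai.ci_high) - np.log(nai.ci_low)
        assert len_sel >= len_nai - 1e-9

    def test_strong_signal_selective_excludes_one(self, rng):
        path = self._fit_path(rng, n=4000, beta=(0.8, 0.0, 0.0))
        sel = selective_inference(path, k=1)[0]
        assert sel.variable == "x0"
        assert sel.ci_low > 1.0 and sel.p_value < 0.01


class TestBonferroni:
    def _naive(self):
        return [EffectEstimate("x", 1.5, 1.1, 2.05, p_value=0.02, method="naive_wald", se=0.16)]

    def test_single_candidate_unchanged(self):
        out = bonferroni_refit(self._naive(), 1)[0]
        assert out.p_value == pytest.approx(0.02)
        assert out.ci_low == pytest.approx(1.1, rel=0.02)

    def test_p_multiplied_and_capped(self):
        assert bonferroni_refit(self._naive(), 6)[0].p_value == pytest.approx(0.12)
        big = [EffectEstimate("x", 1.5, 1.1, 2.0, p_value=0.4, method="naive_wald", se=0.2)]
        assert bonferroni_refit(big, 6)[0].p_value == 1.0

    def test_corrected_interval_contains_naive(self):
        naive = self._naive()[0]
        out = bonferroni_refit([naive], 6)[0]
        assert out.ci_low <= naive.ci_low and out.ci_high >= naive.ci_high

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_refit(self._naive(), 0)


class TestPercentileInterval:
    def test_endpoints_are_order_statistics(self, rng):
        x = rng.standard_normal(1000)
        lo, hi = percentile_interval(x, 0.95)
        s = np.sort(x)
        # inverted-CDF quantile: Q(q) = s[ceil(q*n) - 1]
        assert lo == s[int(np.ceil(0.025 * 1000)) - 1]
        assert hi == s[int(np.ceil(0.975 * 1000)) - 1]
        assert lo in x and hi in x


def _design_tables(table, m):
    from slcma.encoding import build_design

    d = build_design(table).reset_index(drop=True)
    return [d.copy() for _ in range(m)]


@pytest.fixture(scope="module")
def small_cohort():
    p = SimulationParams(n_participants=1200, seed=31)
    return simulate_cohort(p)


class TestStackedBootstrap:

    def test_identical_copies_match_plain_bootstrap(self, small_cohort):
        """m identical complete-data copies reduce to the ordinary
        case-resampling bootstrap (same seed, same resampling indices)."""
        tabs5 = _design_tables(small_cohort, 5)
        tabs1 = _design_tables(small_cohort, 1)
        kw = dict(
            outcome="violent_any",
            variables=["accumulation", "poverty_adult"],
            B=200,
            seed=99,
        )
        est5 = stacked_bootstrap(tabs5, **kw)
        est1 = stacked_bootstrap(tabs1, **kw)
        for a, b in zip(est5, est1):
            assert a.odds_ratio == pytest.approx(b.odds_ratio, abs=1e-8)
            assert a.ci_low == pytest.approx(b.ci_low, abs=1e-8)

    def test_seed_determinism(self, small_cohort):
        tabs = _design_tables(small_cohort, 3)
        kw = dict(outcome="violent_any", variables=["accumulation"], B=250, seed=7)
        a = stacked_bootstrap(tabs, **kw)
        b = stacked_bootstrap(tabs, **kw)
        assert a[0].ci_low == b[0].ci_low and a[0].ci_high == b[0].ci_high

    def test_point_estimate_equals_average_data_fit(self, small_cohort):
        """When all imputations agree, the stacked weighted fit equals the
        single-dataset fit."""
        import statsmodels.api as sm

        tabs = _design_tables(small_cohort, 4)
        est = stacked_bootstrap(
            tabs, outcome="violent_any", variables=["accumulation"], B=200, seed=3
        )
        d = tabs[0]
        ref = sm.Logit(
            d["violent_any"], sm.add_constant(d[["accumulation"]])
        ).fit(disp=0)
        assert est[0].log_or == pytest.approx(ref.params["accumulation"], abs=1e-6)

    def test_stars_follow_interval_exclusion(self, small_cohort):
        tabs = _design_tables(small_cohort, 2)
        est = stacked_bootstrap(
            tabs, outcome="violent_any", variables=["accumulation"], B=400, seed=11
        )[0]
        if est.stars == "**":
            lo99, hi99 = est.ci_low, est.ci_high  # 95% within 99% -> also excludes 1
            assert est.ci_low > 1.0 or est.ci_high < 1.0
        if est.stars == "":
            assert est.ci_low <= 1.0 <= est.ci_high

    def test_mismatched_ids_rejected(self, small_cohort):
        tabs = _design_tables(small_cohort, 2)
        tabs[1] = tabs[1].iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="identical participant ids"):
            stacked_bootstrap(tabs, outcome="violent_any", variables=["accumulation"], B=200, seed=1)

    def test_small_B_warns(self, small_cohort):
        tabs = _design_tables(small_cohort, 2)
        with pytest.warns(UserWarning, match="B < 200"):
            stacked_bootstrap(tabs, outcome="violent_any", variables=["accumulation"], B=50, seed=1)
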