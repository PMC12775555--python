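"""Trend, predictability, comparison and mixed-model machinery."""

import math
import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pinkfoot import stats as st


def _series(years, values):
    return pd.Series(values, index=pd.Index(years, name="year"), dtype=float)


YEARS = np.arange(1979, 2023)


class TestTrendAndDetrend:
    def test_exact_line(self):
        s = _series(YEARS, 2.0 * YEARS + 3.0)
        t = st.linear_trend(s)
        assert t.slope == pytest.approx(2.0, abs=1e-10)
        assert st.detrend(s).abs().max() < 1e-9

    def test_constant_series_degenerate(self):
        t = st.linear_trend(_series(YEARS, np.full(len(YEARS), 7.0)))
        assert t.slope == 0.0 and t.degenerate and np.isnan(t.p)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(3)
        s = _series(YEARS, -0.5 * (YEARS - 2000) + rng.normal(0, 2, len(YEARS)))
        t = st.linear_trend(s)
        assert abs(t.slope - (-0.5)) < 0.2
        assert t.se > 0 and 0 <= t.p <= 1

    def test_detrend_idempotent_and_orthogonal(self):
        rng = np.random.default_rng(4)
        s = _series(YEARS, 120 - 0.3 * YEARS + rng.normal(0, 3, len(YEARS)))
        r = st.detrend(s)
        assert abs(r.mean()) < 1e-10
        pd.testing.assert_series_equal(st.detrend(r), r, atol=1e-9)
        # residuals orthogonal to year: regressing them on year gives slope ~ 0
        assert abs(st.linear_trend(r).slope) < 1e-10

    def test_too_few_years(self):
        with pytest.raises(ValueError):
            st.linear_trend(_series([2000, 2001], [1, 2]))


class TestPredictability:
    def test_identity_relation(self):
        rng = np.random.default_rng(5)
        a = st.detrend(_series(YEARS, rng.normal(0, 3, len(YEARS)) + 100))
        r = st.cross_site_predictability(a, a)
        assert r.slope == pytest.approx(1.0, abs=1e-9)
        assert r.p < 0.001

    def test_independent_noise_flat(self):
        rng = np.random.default_rng(6)
        a = _series(YEARS, rng.normal(0, 1, len(YEARS)))
        b = _series(YEARS, rng.normal(0, 1, len(YEARS)))
        r = st.cross_site_predictability(st.detrend(a), st.detrend(b))
        assert abs(r.slope) < 0.4 and r.p > 0.05

    def test_rsquared_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        a = st.detrend(_series(YEARS, rng.normal(0, 2, len(YEARS))))
        b = 0.6 * a + rng.normal(0, 1, len(a))
        r_pred = st.cross_site_predictability(a, b)
        r_cor, _ = st.correlate(a, b)
        # t statistics of slope and correlation coincide for simple OLS
        t_slope = r_pred.slope / r_pred.se
        t_cor = r_cor * math.sqrt((len(a) - 2) / (1 - r_cor ** 2))
        assert t_slope == pytest.approx(t_cor, rel=1e-9)

    def test_period_interaction_detected(self):
        rng = np.random.default_rng(8)
        early = np.arange(1979, 2000)
        late = np.arange(2000, 2023)
        a = _series(YEARS, rng.normal(0, 1, len(YEARS)))
        b_vals = np.where(YEARS < 2000, 0.0 * a.values, -1.0 * a.values) + rng.normal(0, 1, len(YEARS))
        r = st.cross_site_predictability(a, _series(YEARS, b_vals),
                                         periods=(early, late))
        assert r.interaction_p < 0.05
        assert abs(r.period_slopes["early"]) < 0.6
        assert r.period_slopes["late"] < -0.4

    def test_period_with_too_few_years(self):
        a = _series(np.arange(1998, 2004), np.arange(6.0))
        with pytest.raises(ValueError, match="fewer than 3"):
            st.cross_site_predictability(a, a, periods=(range(1979, 2000), range(2000, 2023)))


class TestWithinYearAndCorrelation:
    def test_equals_paired_ttest(self):
        rng = np.random.default_rng(9)
        a = _series(YEARS, rng.normal(100, 5, len(YEARS)))
        b = a + 5 + rng.normal(0, 1, len(YEARS))
        c = st.within_year_difference(a, b)
        t, p = sps.ttest_rel(b.values, a.values)
        assert c.stat == pytest.approx(t, rel=1e-10)
        assert c.p == pytest.approx(p, rel=1e-10)
        assert abs(c.estimate - 5) < 0.6

    def test_identical_series_zero(self):
        a = _series(YEARS[:23], np.linspace(100, 120, 23))
        assert st.within_year_difference(a, a).estimate == 0.0
        with pytest.raises(ValueError):
            st.within_year_difference(a.iloc[:1], a.iloc[:1])

    def test_correlate(self):
        a = _series(YEARS, np.linspace(0, 10, len(YEARS)))
        assert st.correlate(a, a)[0] == pytest.approx(1.0)
        assert st.correlate(a, -a)[0] == pytest.approx(-1.0)
        rng = np.random.default_rng(10)
        x = rng.normal(size=(len(YEARS), 2))
        z = 0.5 * x[:, 0] + math.sqrt(1 - 0.25) * x[:, 1]
        r, p = st.correlate(_series(YEARS, x[:, 0]), _series(YEARS, z))
        assert 0.2 <= r <= 0.75
        with pytest.raises(ValueError, match="variance"):
            st.correlate(_series(YEARS, np.ones(len(YEARS))), a)


def _glmm_data(seed=5, n=120, beta_area=1.0, sd_year=0.8, sd_ind=1.0):
    rng = np.random.default_rng(seed)
    year = rng.integers(2015, 2021, n)
    ind = rng.integers(0, 40, n)
    yr_eff = {y: rng.normal(0, sd_year) for y in sorted(set(year))}
    ind_eff = {i: rng.normal(0, sd_ind) for i in sorted(set(ind))}
    area = rng.random(n) < 0.5
    eta = -0.3 + beta_area * area + np.array([yr_eff[y] for y in year]) \
        + np.array([ind_eff[i] for i in ind])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"attempted": y, "area": np.where(area, "new", "trad"),
                         "year": year, "animal_id": [f"g{i}" for i in ind]})


class TestMixedModels:
    def test_binomial_zero_variance_matches_analytic_logodds(self):
        rows = []
        for area, k, n in [("A", 30, 50), ("B", 20, 50)]:
            for i in range(n):
                rows.append({"attempted": int(i < k), "area": area,
                             "year": 2000 + i % 5, "animal_id": f"{area}{i}"})
        d = pd.DataFrame(rows)
        fit = st.fit_mixed(st.MixedModelSpec("attempted", "C(area)",
                                             ("year", "animal_id"), "binomial"), d)
        analytic = math.log(20 / 30) - math.log(30 / 20)
        assert fit.term("C(area)[T.B]").estimate == pytest.approx(analytic, abs=1e-3)
        assert all(s < 0.01 for s in fit.random_sd.values())

    def test_binomial_agrees_with_lme4_glmer(self):
        """Independent oracle: lme4's Laplace fit of the same GLMM."""
        d = _glmm_data()
        fit = st.fit_mixed(st.MixedModelSpec("attempted", "C(area)",
                                             ("year", "animal_id"), "binomial"), d)
        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, "d.csv")
            d.to_csv(path, index=False)
            script = (
                'suppressMessages(library(lme4));'
                f'd <- read.csv("{path}");'
                'm <- glmer(attempted ~ area + (1|year) + (1|animal_id),'
                ' data=d, family=binomial);'
                'cat(fixef(m)["areatrad"], as.data.frame(VarCorr(m))$sdcor, sep="\\n")'
            )
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=300, check=True)
        beta_r, sd_ind_r, sd_year_r = (float(x) for x in out.stdout.split())
        assert fit.term("C(area)[T.trad]").estimate == pytest.approx(beta_r, abs=0.06)
        assert fit.random_sd["animal_id"] == pytest.approx(sd_ind_r, abs=0.05)
        assert fit.random_sd["year"] == pytest.approx(sd_year_r, abs=0.05)

    def test_gaussian_lmm_recovers_area_effect(self):
        rng = np.random.default_rng(7)
        n = 90
        years = rng.integers(2015, 2023, n)
        inds = [f"g{i}" for i in rng.integers(0, 45, n)]
        yr_eff = {y: rng.normal(0, 2) for y in sorted(set(years))}
        ind_eff = {i: rng.normal(0, 3) for i in sorted(set(inds))}
        new = rng.random(n) < 0.5
        laying = 150 + 3.5 * new + np.array([yr_eff[y] for y in years]) \
            + np.array([ind_eff[i] for i in inds]) + rng.normal(0, 4, n)
        d = pd.DataFrame({"laying": laying, "area": np.where(new, "new", "trad"),
                          "year": years, "animal_id": inds})
        fit = st.fit_mixed(st.MixedModelSpec("laying", "C(area)",
                                             ("year", "animal_id"), "gaussian"), d)
        est = -fit.term("C(area)[T.trad]").estimate  # trad is reference-coded second
        assert est == pytest.approx(3.5, abs=1.5)
        assert fit.term("C(area)[T.trad]").se > 0
        assert 0 <= fit.term("C(area)[T.trad]").p <= 1

    def test_single_level_groups_degrade_to_fixed_effects(self):
        rng = np.random.default_rng(11)
        d = pd.DataFrame({"y": rng.normal(0, 1, 40), "x": rng.normal(0, 1, 40),
                          "year": 2020, "animal_id": "g0"})
        with pytest.warns(UserWarning, match="dropped"):
            fit = st.fit_mixed(st.MixedModelSpec("y", "x", ("year", "animal_id"),
                                                 "gaussian"), d)
        assert fit.degraded_to_fixed
        import statsmodels.formula.api as smf
        ols = smf.ols("y ~ x", d).fit()
        assert fit.term("x").estimate == pytest.approx(ols.params["x"], rel=1e-9)

    def test_identical_groups_zero_effect(self):
        """Areas with identical response patterns give a zero area contrast."""
        rows = []
        for area in ("A", "B"):
            for i in range(50):
                rows.append({"attempted": int(i < 25), "area": area,
                             "year": 2000 + i % 5, "animal_id": f"{area}{i}"})
        fit = st.fit_mixed(st.MixedModelSpec("attempted", "C(area)",
                                             ("year", "animal_id"), "binomial"),
                           pd.DataFrame(rows))
        assert abs(fit.term("C(area)").estimate) < 1e-4


class TestAssembledModels:
    def test_propensity_declines_with_relative_arrival(self):
        rng = np.random.default_rng(15)
        n = 300
        rel = rng.normal(0, 8, n)
        year = rng.integers(2015, 2023, n)
        eta = 0.5 - 0.12 * rel
        att = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        d = pd.DataFrame({"attempted": att, "area": np.where(rng.random(n) < 0.5, "new", "trad"),
                          "relative_arrival": rel, "year": year,
                          "animal_id": [f"g{i}" for i in range(n)]})
        fit = st.propensity_model(d, onset_col=None, extra="relative_arrival")
        c = fit.term("relative_arrival")
        assert c.estimate < 0 and c.p < 0.05

    def test_success_model_onset_effect(self):
        """Nesting success declining with later (scaled) spring onset is recovered."""
        rng = np.random.default_rng(17)
        n = 240
        onset = rng.normal(150, 6, n)
        z = (onset - onset.mean()) / onset.std(ddof=1)
        eta = 0.2 - 1.2 * z
        succ = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        d = pd.DataFrame({"success": succ, "onset_day": onset,
                          "area": np.where(rng.random(n) < 0.5, "new", "trad"),
                          "year": rng.integers(2015, 2023, n),
                          "animal_id": [f"g{i}" for i in range(n)]})
        fit = st.success_model(d)
        c = fit.term("onset_day")
        assert c.estimate == pytest.approx(-1.2, abs=0.5)
        assert c.p < 0.05

    def test_juvenile_model_recovers_slope(self):
        rng = np.random.default_rng(16)
        years = np.arange(2000, 2023)
        rows = []
        for pop in ("traditional", "new"):
            onset = rng.normal(150, 8, len(years))
            juv = 1.0 - 0.005 * onset + rng.normal(0, 0.02, len(years))
            for y, o, j in zip(years, onset, juv):
                rows.append({"population": pop, "year": y, "onset_day": o,
                             "juvenile_proportion": j})
        res = st.juvenile_model(pd.DataFrame(rows))
        slope = next(c for c in res if c.term == "onset_day")
        assert slope.estimate == pytest.approx(-0.005, abs=0.002)

    def test_missing_covariates_raise(self):
        with pytest.raises(ValueError, match="missing"):
            st.juvenile_model(pd.DataFrame({"year": [1, 2]}))


def test_interaction_power_at_generating_slopes():
    """Slopes (0, -1), noise sd 1, n=21+23: interaction detected in >=80% of seeds."""
    detected = 0
    n_seeds = 200
    early = np.arange(1979, 2000)
    late = np.arange(2000, 2023)
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        a = _series(YEARS, rng.normal(0, 1, len(YEARS)))
        b = _series(YEARS, np.where(YEARS < 2000, 0.0, -1.0) * a.values
                    + rng.normal(0, 1, len(YEARS)))
        r = st.cross_site_predictability(a, b, periods=(early, late))
        detected += r.interaction_p < 0.05
    assert detected / n_seeds >= 0.80
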