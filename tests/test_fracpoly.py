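"""Fractional-polynomial basis, fitting, and closed-test model selection."""

import numpy as np
import pandas as pd
import pytest

import lifespanvol as lv
from lifespanvol.fracpoly import FPSpec, fp_basis, fit_fp, select_fp, fit_fp_by_sex


def _sim(rng, n, f, noise, n_sites=8):
    age = rng.uniform(5, 85, n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    sites = rng.choice([f"s{i}" for i in range(n_sites)], n)
    y = f(age) + rng.normal(0, noise, n)
    return y, age, sex, sites


class TestBasis:
    def test_log_and_sqrt_columns(self):
        assert fp_basis(np.e, (0.0,))[0, 0] == pytest.approx(1.0)
        assert fp_basis(4.0, (0.5,))[0, 0] == pytest.approx(2.0)

    def test_repeated_power_multiplies_by_log(self):
        cols = fp_basis(2.0, (1.0, 1.0))
        assert cols[0, 0] == pytest.approx(2.0)
        assert cols[0, 1] == pytest.approx(2.0 * np.log(2.0))

    def test_identity_power_reproduces_input(self, rng):
        x = rng.uniform(0.5, 9, 50)
        np.testing.assert_allclose(fp_basis(x, (1.0,))[:, 0], x)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError, match="x > 0"):
            fp_basis(np.array([1.0, -2.0]), (1.0,))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FPSpec((1.0, 0.5))  # unsorted
        with pytest.raises(ValueError):
            FPSpec((0.25,))  # off-grid power
        assert FPSpec((0.0, 1.0)).degree == 2


class TestFitFP:
    def test_exact_linear_fit_has_zero_rss(self, rng):
        y, age, sex, sites = _sim(rng, 500, lambda a: 10 + 3 * a, 0.0)
        fit = fit_fp(y, age, None, sites, FPSpec((1.0,)), include_sex=False)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.partial_r2_age == pytest.approx(1.0, abs=1e-12)
        # with a sex covariate the age-attributable share stays essentially 1
        fit2 = fit_fp(y, age, sex, sites, FPSpec((1.0,)))
        assert fit2.partial_r2_age > 0.99

    def test_pure_noise_has_negligible_partial_r2(self, rng):
        y, age, sex, sites = _sim(rng, 10000, lambda a: 0 * a + 50, 10.0)
        fit = fit_fp(y, age, sex, sites, FPSpec((1.0,)))
        assert fit.partial_r2_age < 0.002

    def test_single_site_warns_but_fits(self, rng):
        y, age, sex, sites = _sim(rng, 200, lambda a: a, 1.0, n_sites=1)
        with pytest.warns(UserWarning, match="single site"):
            fit = fit_fp(y, age, sex, sites, FPSpec((1.0,)))
        assert fit.n_sites == 1
        assert np.all(np.isfinite(fit.robust_se))

    def test_deviance_nonincreasing_in_degree(self, rng):
        y, age, sex, sites = _sim(rng, 2000, lambda a: 3000 / a + 20 * a, 5.0)
        devs = []
        from lifespanvol.fracpoly import _best_of_degree

        for m in (1, 2, 3):
            _, rss = _best_of_degree(y, age, sex, m, 10.0)
            devs.append(len(y) * np.log(rss / len(y)))
        assert devs[0] >= devs[1] >= devs[2]


class TestSelectFP:
    def test_linear_truth_selects_straight_line(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, age, sex, sites = _sim(rng, 2000, lambda a: 100 + 2 * a, 0.01 * 160)
            fit = select_fp(y, age, sex, sites)
            hits += fit.spec.powers == (1.0,)
        assert hits >= 9

    def test_curved_truth_recovers_shape(self, rng):
        truth = lambda a: 500 * (a / 10) ** -2 + 30 * (a / 10)
        y, age, sex, sites = _sim(rng, 5000, truth, 10.0)
        fit = select_fp(y, age, sex, sites)
        assert fit.spec.degree >= 2
        grid = np.linspace(5, 85, 100)
        rmse = np.sqrt(np.mean((fit.predict(grid) - truth(grid)) ** 2))
        assert rmse <= 0.02 * np.ptp(truth(grid))

    def test_zero_noise_is_degenerate(self, rng):
        y, age, sex, sites = _sim(rng, 500, lambda a: 2 * a, 0.0)
        with pytest.raises(ValueError, match="jitter"):
            select_fp(y, age, sex, sites)

    def test_null_truth_rarely_admits_age_term(self):
        # type-I behaviour of the closed test at alpha=0.05, 200 replicates
        admitted = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            y, age, sex, sites = _sim(rng, 300, lambda a: 0 * a + 50, 5.0)
            fit = select_fp(y, age, sex, sites, alpha=0.05)
            admitted += fit.spec.degree >= 1
        assert admitted / reps <= 0.09  # ~alpha with binomial slack

    def test_selection_trace_gates_on_age_free_comparison(self, rng):
        y, age, sex, sites = _sim(rng, 1000, lambda a: 50 + 0 * a, 5.0)
        fit = select_fp(y, age, sex, sites)
        assert fit.selection_trace[0]["comparison"] == "FP3 vs age-free"
        assert not fit.selection_trace[0]["significant"]
        assert len(fit.selection_trace) == 1  # closed test stops at the gate
        # a strongly linear signal walks the full sequence down to the line
        y2, age2, sex2, sites2 = _sim(rng, 1000, lambda a: 50 + 3 * a, 1.0)
        fit2 = select_fp(y2, age2, sex2, sites2)
        comps = [t["comparison"] for t in fit2.selection_trace]
        assert comps[:2] == ["FP3 vs age-free", "FP3 vs line"]
        assert fit2.spec.powers == (1.0,)


class TestAgebandCorrelations:
    def _table(self, y, age, sex):
        return pd.DataFrame({"age": age, "sex": sex, "vol": y})

    def test_perfect_positive_and_negative(self, rng):
        age = rng.uniform(6, 90, 600)
        sex = np.where(rng.random(600) < 0.5, "M", "F")
        t = self._table(age.copy(), age, sex)
        out = lv.ageband_correlations(t, "vol")
        assert np.allclose(out.loc[out.group == "all", "r"], 1.0)
        t2 = self._table(-age + rng.normal(0, 1e-9, 600), age, sex)
        out2 = lv.ageband_correlations(t2, "vol")
        assert np.allclose(out2.loc[out2.group == "all", "r"], -1.0, atol=1e-6)

    def test_known_correlation_recovered(self, rng):
        rows = []
        for lo, hi in ((6, 29), (30, 59), (60, 90)):
            n = 5000
            age = rng.uniform(lo, hi, n)
            z = (age - age.mean()) / age.std()
            y = -0.3 * z + np.sqrt(1 - 0.09) * rng.standard_normal(n)
            rows.append(pd.DataFrame({"age": age, "sex": "M", "vol": y}))
        t = pd.concat(rows, ignore_index=True)
        out = lv.ageband_correlations(t, "vol")
        pooled = out[(out.group == "all")]
        assert np.allclose(pooled["r"], -0.3, atol=0.04)

    def test_degenerate_band_reports_missing(self):
        t = self._table([1.0, 1.0, 1.0], [10.0, 15.0, 20.0], ["M", "M", "F"])
        out = lv.ageband_correlations(t, "vol")
        assert out.loc[(out.band == "early") & (out.group == "all"), "r"].isna().all()


class TestFitBySex:
    def test_all_male_input_skips_female(self, rng):
        y, age, sex, sites = _sim(rng, 800, lambda a: 100 + 2 * a, 3.0)
        sex = np.array(["M"] * 800)
        with pytest.warns(UserWarning, match="'F'"):
            fits = fit_fp_by_sex(y, age, sex, sites)
        assert fits["F"] is None
        pooled = select_fp(y, age, None, sites, include_sex=False)
        assert fits["M"].spec.powers == pooled.spec.powers
        np.testing.assert_allclose(fits["M"].coefficients, pooled.coefficients)

    def test_additive_sex_effect_gives_parallel_curves(self, rng):
        age = rng.uniform(5, 85, 6000)
        sex = np.where(rng.random(6000) < 0.5, "M", "F")
        sites = rng.choice(list("abcd"), 6000)
        y = 1000 + 5 * age + 200 * (sex == "M") + rng.normal(0, 20, 6000)
        fits = fit_fp_by_sex(y, age, sex, sites)
        grid = np.linspace(10, 80, 50)
        gap = fits["M"].predict(grid) - fits["F"].predict(grid)
        assert np.ptp(gap) < 25.0  # constant separation within noise tolerance
        assert gap.mean() == pytest.approx(200.0, abs=15.0)

    def test_no_sex_effect_curves_agree_within_error(self, rng):
        age = rng.uniform(5, 85, 6000)
        sex = np.where(rng.random(6000) < 0.5, "M", "F")
        sites = rng.choice(list("abcd"), 6000)
        y = 1000 + 5 * age + rng.normal(0, 20, 6000)
        fits = fit_fp_by_sex(y, age, sex, sites)
        grid = np.linspace(10, 80, 50)
        gap = np.abs(fits["M"].predict(grid) - fits["F"].predict(grid))
        assert gap.max() < 2 * 20.0 / np.sqrt(3000 / 50) * 4  # loose 2-SE style band
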