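"""Empirical-Bayes site harmonization: oracles, invariants, and an external
cross-check against the reference R implementation (sva::ComBat)."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

import lifespanvol as lv
from lifespanvol.combat import apply_combat, build_design, fit_combat


class TestBuildDesign:
    def test_centered_ages_prune_age_columns(self):
        X, names = build_design([45.0] * 4, ["M", "F", "M", "F"])
        assert names == ["intercept", "sex"]
        assert np.linalg.matrix_rank(X) == 2

    def test_full_rank_five_columns(self, rng):
        ages = rng.uniform(5, 85, 100)
        sexes = np.where(rng.random(100) < 0.5, "M", "F")
        X, names = build_design(ages, sexes)
        assert X.shape[1] == 5
        assert np.linalg.matrix_rank(X) == 5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_design([], [])

    def test_constant_sex_dropped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="sex"):
            X, names = build_design(rng.uniform(5, 85, 20), ["M"] * 20)
        assert "sex" not in names


def _shifted_toy(rng, shift=10.0, n=50, f=3):
    b1 = rng.normal(0.0, 1.0, (f, n))
    data = np.hstack([b1, b1 + shift])
    batches = ["a"] * n + ["b"] * n
    design = np.ones((2 * n, 1))
    return data, batches, design


class TestFitApplyCombat:
    def test_location_shift_removed_exactly_without_shrinkage(self, rng):
        data, batches, design = _shifted_toy(rng)
        m = fit_combat(data, batches, design, eb=False)
        adj = apply_combat(m, data, batches, design)
        gap = np.abs(adj[:, :50].mean(axis=1) - adj[:, 50:].mean(axis=1))
        assert gap.max() < 1e-6

    def test_eb_path_removes_nearly_all_of_the_shift(self, rng):
        data, batches, design = _shifted_toy(rng)
        m = fit_combat(data, batches, design)
        adj = apply_combat(m, data, batches, design)
        gap = np.abs(adj[:, :50].mean(axis=1) - adj[:, 50:].mean(axis=1)).max()
        assert gap < 0.01 * 10.0  # >99% of the 10-unit shift removed

    def test_no_true_site_effect_shrinks_gamma(self, rng):
        data = rng.normal(0, 1, (3, 4000))
        batches = ["a"] * 2000 + ["b"] * 2000
        design = np.ones((4000, 1))
        m = fit_combat(data, batches, design)
        pre = np.abs(data[:, :2000].mean(1) - data[:, 2000:].mean(1)).max()
        adj = apply_combat(m, data, batches, design)
        post = np.abs(adj[:, :2000].mean(1) - adj[:, 2000:].mean(1)).max()
        assert np.abs(m.gamma_star).max() < 0.05
        assert post < pre

    def test_huge_tolerance_stops_after_one_iteration(self, rng):
        data, batches, design = _shifted_toy(rng)
        m = fit_combat(data, batches, design, tol=1e9)
        assert m.n_iter == 1

    def test_identity_adjustment_returns_input(self, rng):
        data, batches, design = _shifted_toy(rng)
        m = fit_combat(data, batches, design)
        m.gamma_star = np.zeros_like(m.gamma_star)
        m.delta_star = np.ones_like(m.delta_star)
        adj = apply_combat(m, data, batches, design)
        # removing nothing in standardized space restores the data
        np.testing.assert_allclose(adj, data, atol=1e-10)

    def test_refit_on_harmonized_output_is_fixed_point(self, rng):
        data = rng.normal(0, 1, (5, 3000)) + np.array([[2.0], [1.0], [0.0], [-1.0], [3.0]])
        batches = np.array(["a"] * 1000 + ["b"] * 1000 + ["c"] * 1000)
        shifts = {"a": 0.0, "b": 4.0, "c": -2.0}
        data = data + np.array([shifts[b] for b in batches])[None, :]
        design = np.ones((3000, 1))
        m = fit_combat(data, batches, design)
        adj = apply_combat(m, data, batches, design)
        m2 = fit_combat(adj, batches, design)
        assert np.abs(m2.gamma_star).max() < 0.05
        assert np.abs(m2.delta_star - 1.0).max() < 0.05

    def test_errors(self, rng):
        data, batches, design = _shifted_toy(rng)
        with pytest.raises(ValueError, match="unseen"):
            apply_combat(fit_combat(data, batches, design), data, ["zz"] * 100, design)
        with pytest.raises(ValueError, match="single subject"):
            m = fit_combat(data, batches, design)
            apply_combat(m, data[:, :3], ["a", "a", "b"], design[:3])
        const = data.copy()
        const[0, :50] = 5.0  # zero variance in batch a, feature 0
        with pytest.raises(ValueError, match="zero variance"):
            fit_combat(const, batches, design)
        with pytest.raises(ValueError, match=">= 2 batches"):
            fit_combat(data, ["a"] * 100, design)


def linear_trajectory_cohort(seed=21, n_sites=20, site_n=300, shift_sd=400.0):
    """Linear age trajectory, overlapping site age windows, strong site
    effects: the regime where harmonization must preserve the age signal."""
    from lifespanvol.cohort import SimConfig

    cfg = SimConfig(
        n_sites=n_sites,
        site_sizes=(site_n,) * n_sites,
        site_age_ranges=((5.0, 85.0),) * n_sites,
        site_shift_sd=shift_sd,
        site_scale_range=(0.85, 1.15),
        noise_sd_base=300.0,
        hetero_slope=0.0,
        outlier_rate=0.0,
        seed=seed,
    )
    traj = {r: lv.TrajectoryParams("monotonic_increase", level=1000.0, decline_rate=20.0,
                                   sex_effect=100.0)
            for r in lv.REGIONS}
    return lv.generate_cohort(cfg, traj)


class TestHarmonizeTable:
    def test_between_site_variance_reduced_and_slope_preserved(self):
        t = linear_trajectory_cohort(seed=21)
        t, _ = lv.filter_complete(t)
        t, _ = lv.adjust_icv(t)
        harm, model = lv.harmonize_table(t)
        col = "thalamus_L"

        def site_mean_resid_var(tab):
            X, _ = build_design(tab["age"], tab["sex"])
            beta, *_ = np.linalg.lstsq(X, tab[col].to_numpy(), rcond=None)
            r = tab[col].to_numpy() - X @ beta
            import pandas as pd

            return pd.Series(r).groupby(tab["site_id"].to_numpy()).mean().var()

        assert site_mean_resid_var(harm) < 0.1 * site_mean_resid_var(t)

        A = np.column_stack([np.ones(len(harm)), harm["age"]])
        slope_fit = np.linalg.lstsq(A, harm[col].to_numpy(), rcond=None)[0][1]
        assert slope_fit == pytest.approx(20.0, rel=0.05)

    def test_shape_and_order_preserved(self, clean_cohort):
        harm, _ = lv.harmonize_table(clean_cohort)
        assert harm.shape == clean_cohort.shape
        assert list(harm.columns) == list(clean_cohort.columns)
        assert (harm["participant_id"] == clean_cohort["participant_id"]).all()

    def test_single_site_passthrough_with_warning(self, clean_cohort):
        one = clean_cohort[clean_cohort["site_id"] == clean_cohort["site_id"].iloc[0]]
        with pytest.warns(UserWarning, match="single site"):
            harm, model = lv.harmonize_table(one)
        np.testing.assert_allclose(
            harm["thalamus_L"].to_numpy(), one["thalamus_L"].to_numpy()
        )
        assert model.single_batch

    def test_per_hemisphere_mode(self, clean_cohort):
        harm, models = lv.harmonize_table(clean_cohort, per_hemisphere=True)
        assert len(models) == 2
        assert harm.shape == clean_cohort.shape


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_reference_r_implementation(tmp_path, rng):
    """Independent oracle: sva::ComBat on a small fixture with one covariate."""
    n1, n2, f = 40, 60, 5
    x = rng.uniform(-1, 1, n1 + n2)
    data = rng.normal(0, 1, (f, n1 + n2)) + np.outer(rng.normal(1, 0.3, f), x)
    data[:, n1:] = data[:, n1:] * 1.6 + 3.0
    np.savetxt(tmp_path / "dat.csv", data, delimiter=",")
    (tmp_path / "batch.txt").write_text("\n".join(["a"] * n1 + ["b"] * n2))
    np.savetxt(tmp_path / "cov.txt", x)
    script = textwrap.dedent(
        """
        suppressMessages(library(sva))
        d <- as.matrix(read.csv(file.path("%s", "dat.csv"), header=FALSE))
        b <- scan(file.path("%s", "batch.txt"), what="character", quiet=TRUE)
        x <- scan(file.path("%s", "cov.txt"), quiet=TRUE)
        mod <- model.matrix(~x)
        out <- ComBat(dat=d, batch=b, mod=mod, par.prior=TRUE)
        write.csv(out, file.path("%s", "ref.csv"), row.names=FALSE)
        """
        % ((tmp_path,) * 4)
    )
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
    import pandas as pd

    ref = pd.read_csv(tmp_path / "ref.csv").to_numpy()
    design = np.column_stack([np.ones(len(x)), x])
    model = fit_combat(data, ["a"] * n1 + ["b"] * n2, design)
    mine = apply_combat(model, data, ["a"] * n1 + ["b"] * n2, design)
    np.testing.assert_allclose(mine, ref, atol=1e-6)
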