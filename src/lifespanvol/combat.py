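"""Parametric empirical-Bayes (ComBat) site harmonization.

Removes per-site additive (location) and multiplicative (scale) effects from
a features x subjects matrix while preserving covariates of interest (sex and
a smooth age basis).  Per-site, per-feature effects are first estimated by
least squares after standardization, then shrunk across features towards
site-level priors: a normal prior for locations, an inverse-gamma prior for
scales, both with method-of-moments hyperparameters, iterated to convergence
of the conditional posterior means.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VOLUME_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_AGE_CENTER = 45.0
DEFAULT_AGE_SCALE = 45.0


def build_design(
    ages,
    sexes,
    age_degree: int = 3,
    age_center: float = DEFAULT_AGE_CENTER,
    age_scale: float = DEFAULT_AGE_SCALE,
) -> tuple[np.ndarray, list[str]]:
    """Covariate design preserved by harmonization.

    Columns: intercept, sex contrast (+0.5 male / -0.5 female), and powers
    1..``age_degree`` of ``(age - age_center) / age_scale``.  Constant
    columns (a single sex, or all ages at the center) are pruned with a
    warning so the matrix returned has full column rank.
    """
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    if len(ages) == 0:
        raise ValueError("empty input")
    if len(ages) != len(sexes):
        raise ValueError("ages and sexes must have equal length")
    if np.isnan(ages).any():
        raise ValueError("missing ages")
    bad = ~np.isin(sexes, ("M", "F"))
    if bad.any():
        raise ValueError(f"sex values must be 'M' or 'F'; offending rows {np.where(bad)[0][:5]}")

    cols = [np.ones_like(ages)]
    names = ["intercept"]
    sex_col = np.where(sexes == "M", 0.5, -0.5)
    if np.unique(sex_col).size > 1:
        cols.append(sex_col)
        names.append("sex")
    else:
        warnings.warn("constant sex; sex column dropped from design")
    a = (ages - age_center) / age_scale
    for p in range(1, age_degree + 1):
        col = a**p
        if np.ptp(col) > 0:
            cols.append(col)
            names.append(f"age^{p}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


@dataclass
class CombatModel:
    """Fitted harmonization model (all arrays are per batch and/or feature)."""

    batch_labels: list[str]
    feature_names: list[str]
    design_names: list[str]
    beta_covariates: np.ndarray  # (p_cov, F) coefficients of non-intercept design cols
    grand_mean: np.ndarray  # (F,)
    var_pooled: np.ndarray  # (F,)
    gamma_star: np.ndarray  # (B, F) EB-shrunk locations
    delta_star: np.ndarray  # (B, F) EB-shrunk scales (variances)
    gamma_bar: np.ndarray  # (B,) location prior means
    tau2: np.ndarray  # (B,) location prior variances
    a_prior: np.ndarray  # (B,) inverse-gamma shape
    b_prior: np.ndarray  # (B,) inverse-gamma rate
    batch_sizes: np.ndarray  # (B,)
    n_iter: int
    tol: float
    single_batch: bool = False

    def to_json(self, path) -> None:
        payload = {
            "batch_labels": self.batch_labels,
            "feature_names": self.feature_names,
            "design_names": self.design_names,
            "grand_mean": self.grand_mean.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "beta_covariates": self.beta_covariates.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "hyperparameters": {
                "gamma_bar": self.gamma_bar.tolist(),
                "tau2": self.tau2.tolist(),
                "a_prior": self.a_prior.tolist(),
                "b_prior": self.b_prior.tolist(),
            },
            "batch_sizes": self.batch_sizes.tolist(),
            "n_iter": self.n_iter,
            "tol": self.tol,
            "single_batch": self.single_batch,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _batch_onehot(batches: np.ndarray, labels: list[str]) -> np.ndarray:
    return np.column_stack([(batches == lab).astype(float) for lab in labels])


def fit_combat(
    data: np.ndarray,
    batches,
    design: np.ndarray,
    design_names: list[str] | None = None,
    feature_names: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    eb: bool = True,
) -> CombatModel:
    """Fit parametric ComBat on a features x subjects matrix.

    ``design`` must contain an intercept as its first column; the remaining
    columns are the covariates whose signal is preserved.  Requires >= 2
    batches with >= 2 subjects each and nonzero within-batch variance for
    every feature.  ``eb=False`` skips the empirical-Bayes shrinkage and
    uses the per-batch least-squares location/scale estimates directly
    (exact mean/variance matching after standardization).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D features x subjects matrix")
    n_features, n_subjects = data.shape
    batches = np.asarray(batches).astype(str)
    if batches.shape[0] != n_subjects:
        raise ValueError("batches length must equal the number of subjects")
    labels = sorted(set(batches.tolist()))
    sizes = np.array([(batches == lab).sum() for lab in labels], dtype=float)
    if len(labels) < 2:
        raise ValueError("need >= 2 batches; use harmonize_table for single-site pass-through")
    if (sizes < 2).any():
        small = [lab for lab, s in zip(labels, sizes) if s < 2]
        raise ValueError(f"batches with < 2 subjects: {small}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    if design_names is None:
        design_names = [f"x{i}" for i in range(design.shape[1])]

    B = _batch_onehot(batches, labels)
    cov = design[:, 1:]  # drop intercept; batch indicators absorb it
    X = np.hstack([B, cov])
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    nb = len(labels)
    gamma_hat_ls = beta[:nb, :]  # (B, F) batch intercepts
    beta_cov = beta[nb:, :]  # (p_cov, F)

    grand_mean = (sizes / n_subjects) @ gamma_hat_ls  # (F,)
    fitted = X @ beta
    resid = data.T - fitted
    var_pooled = (resid**2).mean(axis=0)  # (F,)
    if (var_pooled <= 0).any():
        idx = int(np.argmin(var_pooled))
        raise ValueError(f"feature {feature_names[idx]!r} has zero pooled variance")

    stand_mean = grand_mean[None, :] + cov @ beta_cov  # (S, F)
    Z = (data.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # (S, F)

    gamma_hat = np.vstack([Z[batches == lab].mean(axis=0) for lab in labels])
    delta_hat = np.vstack([Z[batches == lab].var(axis=0, ddof=1) for lab in labels])
    for bi, lab in enumerate(labels):
        # delta is on the standardized scale, so ~1 for healthy features
        if (delta_hat[bi] <= 1e-10).any():
            fi = int(np.argmin(delta_hat[bi]))
            raise ValueError(
                f"batch {lab!r} has zero variance in feature {feature_names[fi]!r}"
            )

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    # Degenerate prior spread (identical features): skip shrinkage.
    eb_ok = eb and n_features > 1 and np.all(delta_hat.var(axis=1, ddof=1) > 0)
    if eb_ok:
        a_prior = np.array([_aprior(delta_hat[bi]) for bi in range(nb)])
        b_prior = np.array([_bprior(delta_hat[bi]) for bi in range(nb)])
    else:
        if eb and not eb_ok:
            warnings.warn("degenerate across-feature spread; EB shrinkage skipped")
        a_prior = np.zeros(nb)
        b_prior = np.zeros(nb)
        return CombatModel(
            batch_labels=labels,
            feature_names=list(feature_names),
            design_names=list(design_names),
            beta_covariates=beta_cov,
            grand_mean=grand_mean,
            var_pooled=var_pooled,
            gamma_star=gamma_hat,
            delta_star=delta_hat,
            gamma_bar=gamma_bar,
            tau2=tau2,
            a_prior=a_prior,
            b_prior=b_prior,
            batch_sizes=sizes,
            n_iter=0,
            tol=tol,
        )

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    worst_iter = 0
    for bi, lab in enumerate(labels):
        zb = Z[batches == lab]
        n_b = zb.shape[0]
        g_old = gamma_hat[bi].copy()
        d_old = delta_hat[bi].copy()
        count = 0
        while count < max_iter:
            count += 1
            g_new = (tau2[bi] * n_b * gamma_hat[bi] + d_old * gamma_bar[bi]) / (
                tau2[bi] * n_b + d_old
            )
            sum2 = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior[bi]) / (n_b / 2.0 + a_prior[bi] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / np.abs(d_old)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[bi] = g_old
        delta_star[bi] = d_old
        worst_iter = max(worst_iter, count)

    return CombatModel(
        batch_labels=labels,
        feature_names=list(feature_names),
        design_names=list(design_names),
        beta_covariates=beta_cov,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        batch_sizes=sizes,
        n_iter=worst_iter,
        tol=tol,
    )


def apply_combat(
    model: CombatModel, data: np.ndarray, batches, design: np.ndarray
) -> np.ndarray:
    """Remove EB batch effects from ``data`` (features x subjects).

    Standardizes with the fitted grand parameters, subtracts the EB location
    and divides by the EB scale of each subject's batch, then restores the
    covariate structure and pooled scale.
    """
    data = np.asarray(data, dtype=float)
    if model.single_batch:
        return data.copy()
    batches = np.asarray(batches).astype(str)
    unseen = sorted(set(batches.tolist()) - set(model.batch_labels))
    if unseen:
        raise ValueError(f"unseen batch labels: {unseen}")
    for lab in set(batches.tolist()):
        if (batches == lab).sum() < 2:
            raise ValueError(f"batch {lab!r} has a single subject at apply time")
    if data.shape[0] != len(model.feature_names):
        raise ValueError("feature dimension does not match the fitted model")

    cov = design[:, 1:]
    stand_mean = model.grand_mean[None, :] + cov @ model.beta_covariates
    Z = (data.T - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    out = np.empty_like(Z)
    for bi, lab in enumerate(model.batch_labels):
        mask = batches == lab
        if not mask.any():
            continue
        out[mask] = (Z[mask] - model.gamma_star[bi][None, :]) / np.sqrt(
            model.delta_star[bi]
        )[None, :]
    out = out * np.sqrt(model.var_pooled)[None, :] + stand_mean
    return out.T


def harmonize_table(
    table: pd.DataFrame,
    feature_columns: tuple[str, ...] = VOLUME_COLUMNS,
    per_hemisphere: bool = False,
    age_degree: int = 3,
    tol: float = 1e-4,
) -> tuple[pd.DataFrame, CombatModel | list[CombatModel]]:
    """Harmonize the volume columns of a cohort table across sites.

    Pivots to features x subjects, fits ComBat with the default sex + cubic
    age design, and returns the adjusted table together with the model.
    With one site the table passes through unchanged (with a warning).
    ``per_hemisphere=True`` harmonizes the left and right feature sets with
    separate models and returns a list of two models.
    """
    if per_hemisphere:
        out = table.copy()
        models = []
        for h in ("L", "R"):
            cols = tuple(c for c in feature_columns if c.endswith(f"_{h}"))
            out, model = harmonize_table(out, cols, per_hemisphere=False,
                                         age_degree=age_degree, tol=tol)
            models.append(model)
        return out, models

    batches = table["site_id"].astype(str).to_numpy()
    if len(set(batches.tolist())) < 2:
        warnings.warn("single site; harmonization is a pass-through")
        model = CombatModel(
            batch_labels=sorted(set(batches.tolist())),
            feature_names=list(feature_columns),
            design_names=[],
            beta_covariates=np.zeros((0, len(feature_columns))),
            grand_mean=np.zeros(len(feature_columns)),
            var_pooled=np.ones(len(feature_columns)),
            gamma_star=np.zeros((1, len(feature_columns))),
            delta_star=np.ones((1, len(feature_columns))),
            gamma_bar=np.zeros(1),
            tau2=np.zeros(1),
            a_prior=np.zeros(1),
            b_prior=np.zeros(1),
            batch_sizes=np.array([float(len(table))]),
            n_iter=0,
            tol=tol,
            single_batch=True,
        )
        return table.copy(), model

    design, names = build_design(table["age"], table["sex"], age_degree=age_degree)
    data = table[list(feature_columns)].to_numpy(float).T
    model = fit_combat(
        data, batches, design, design_names=names, feature_names=list(feature_columns), tol=tol
    )
    adjusted = apply_combat(model, data, batches, design)
    out = table.copy()
    out[list(feature_columns)] = adjusted.T
    return out, model
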