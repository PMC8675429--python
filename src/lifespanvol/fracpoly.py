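"""Fractional-polynomial (FP) age-trajectory modelling.

An FP of degree m transforms a positive predictor x with powers
(p_1 <= ... <= p_m) drawn from {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where 0
denotes ln x and a repeated power contributes the previous column times
ln x.  Models are fitted by Gaussian least squares with a +-0.5 sex contrast
so the intercept is the cross-sex mean, standard errors are site-clustered
(sandwich), and the degree is chosen by a closed test from degree 3
downwards: chi-square likelihood-ratio tests with 2 df per degree step, a
1-df partial F-test of the best degree-1 FP against the straight line, and
a final F-test of the line against the age-free model, all at a strict
alpha (default 0.01) to avoid overfitting where the age distribution is
dense.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

POWER_GRID: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

DEFAULT_AGE_SCALE = 10.0


@dataclass(frozen=True)
class FPSpec:
    """Powers (sorted ascending, 0 = ln) and the preliminary age divisor."""

    powers: tuple[float, ...]
    age_scale: float = DEFAULT_AGE_SCALE

    def __post_init__(self) -> None:
        if len(self.powers) > 3:
            raise ValueError("degree must be <= 3")
        if tuple(sorted(self.powers)) != tuple(self.powers):
            raise ValueError("powers must be sorted ascending")
        for p in self.powers:
            if p not in POWER_GRID:
                raise ValueError(f"power {p} not in {POWER_GRID}")
        if self.age_scale <= 0:
            raise ValueError("age_scale must be positive")

    @property
    def degree(self) -> int:
        return len(self.powers)


@dataclass(frozen=True)
class AgeBand:
    label: str
    lo: float
    hi: float

    def contains(self, ages) -> np.ndarray:
        ages = np.asarray(ages, float)
        return (ages >= self.lo) & (ages <= self.hi)


DEFAULT_BANDS: tuple[AgeBand, ...] = (
    AgeBand("early", 6.0, 29.0),
    AgeBand("middle", 30.0, 59.0),
    AgeBand("late", 60.0, 90.0),
)


def fp_basis(x, powers) -> np.ndarray:
    """FP basis columns of a positive scalar/vector.

    Column j is x**p_j (ln x for p = 0); a repeated power multiplies the
    previous column by ln x.  ``powers`` may be an FPSpec (in which case x is
    NOT rescaled here; callers divide by ``age_scale`` first) or a sequence.
    """
    if isinstance(powers, FPSpec):
        powers = powers.powers
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("fractional polynomials require x > 0")
    lnx = np.log(x)
    cols: list[np.ndarray] = []
    prev_p: float | None = None
    for p in powers:
        raw = lnx if p == 0 else x**p
        if prev_p is not None and p == prev_p:
            col = cols[-1] * lnx
        else:
            col = raw
        cols.append(col)
        prev_p = p
    if not cols:
        return np.empty((len(x), 0))
    return np.column_stack(cols)


@dataclass
class FPFit:
    """A fitted fractional polynomial for one region-hemisphere series."""

    spec: FPSpec
    coef_names: list[str]
    coefficients: np.ndarray
    rss: float
    deviance: float
    robust_se: np.ndarray
    partial_r2_age: float
    n: int
    n_sites: int
    include_sex: bool
    selection_trace: list[dict] = field(default_factory=list)

    def predict(self, age, sex: str | None = None) -> np.ndarray:
        """Fitted mean curve; ``sex=None`` gives the cross-sex reference
        (sex contrast set to 0)."""
        age = np.atleast_1d(np.asarray(age, float))
        n = len(age)
        cols = [np.ones(n)]
        if self.include_sex:
            if sex is None:
                cols.append(np.zeros(n))
            else:
                cols.append(np.full(n, 0.5 if sex == "M" else -0.5))
        basis = fp_basis(age / self.spec.age_scale, self.spec.powers)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
        return np.column_stack(cols) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "powers": list(self.spec.powers),
            "age_scale": self.spec.age_scale,
            "coef_names": self.coef_names,
            "coefficients": self.coefficients.tolist(),
            "robust_se": self.robust_se.tolist(),
            "rss": self.rss,
            "deviance": self.deviance,
            "partial_r2_age": self.partial_r2_age,
            "n": self.n,
            "n_sites": self.n_sites,
            "selection_trace": self.selection_trace,
        }


def _design(age: np.ndarray, sex, spec: FPSpec, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if sex is not None:
        if isinstance(sex, str):
            sexc = np.full(n, 0.5 if sex == "M" else -0.5)
        else:
            sexc = np.where(np.asarray(sex) == "M", 0.5, -0.5)
        cols.append(sexc)
    basis = fp_basis(age / spec.age_scale, spec.powers)
    for j in range(basis.shape[1]):
        cols.append(basis[:, j])
    return np.column_stack(cols)


def _cluster_robust_se(X: np.ndarray, resid: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Cluster-sandwich SEs by site (HC1-style when there is one cluster)."""
    n, k = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    labels = pd.unique(sites)
    G = len(labels)
    if G > 1:
        meat = np.zeros((k, k))
        for lab in labels:
            m = sites == lab
            s = X[m].T @ resid[m]
            meat += np.outer(s, s)
        c = (G / (G - 1)) * ((n - 1) / max(n - k, 1))
    else:
        meat = (X * (resid**2)[:, None]).T @ X
        c = n / max(n - k, 1)
    cov = c * xtx_inv @ meat @ xtx_inv
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _fit_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("collinear design (degenerate age distribution)")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_fp(y, age, sex, sites, spec: FPSpec, include_sex: bool = True) -> FPFit:
    """Gaussian OLS fit of one FP specification with site-clustered SEs.

    partial_r2_age is the R-squared gain of the full model over the age-free
    (sex-only, or intercept-only) model.
    """
    y = np.asarray(y, float)
    age = np.asarray(age, float)
    sites = np.asarray(sites).astype(str)
    n = len(y)
    if n <= spec.degree + 2:
        raise ValueError("too few observations for the requested degree")
    n_sites = len(set(sites.tolist()))
    if n_sites == 1:
        warnings.warn("single site; robust SEs reduce to heteroscedasticity-robust SEs")

    sexarg = sex if include_sex else None
    X = _design(age, sexarg, spec, n)
    coef, rss = _fit_ols(y, X)
    X0 = _design(age, sexarg, FPSpec(()), n)
    _, rss0 = _fit_ols(y, X0)

    tss = float(np.sum((y - y.mean()) ** 2))
    partial_r2 = 0.0 if tss == 0 else max(0.0, (rss0 - rss) / tss)
    resid = y - X @ coef
    names = ["intercept"] + (["sex"] if include_sex else [])
    names += [f"age_p{p:g}_{j}" for j, p in enumerate(spec.powers)]
    deviance = n * np.log(rss / n) if rss > 0 else -np.inf
    return FPFit(
        spec=spec,
        coef_names=names,
        coefficients=coef,
        rss=rss,
        deviance=float(deviance),
        robust_se=_cluster_robust_se(X, resid, sites),
        partial_r2_age=float(min(1.0, partial_r2)),
        n=n,
        n_sites=n_sites,
        include_sex=include_sex,
    )


def _candidate_specs(degree: int, age_scale: float) -> list[FPSpec]:
    return [
        FPSpec(p, age_scale)
        for p in itertools.combinations_with_replacement(POWER_GRID, degree)
    ]


def _best_of_degree(
    y: np.ndarray, age: np.ndarray, sexarg, degree: int, age_scale: float
) -> tuple[FPSpec, float]:
    """Best (minimum-RSS) FP of the given degree over the power grid."""
    n = len(y)
    best_spec, best_rss = None, np.inf
    for spec in _candidate_specs(degree, age_scale):
        X = _design(age, sexarg, spec, n)
        try:
            _, rss = _fit_ols(y, X)
        except ValueError:
            continue
        if rss < best_rss:
            best_spec, best_rss = spec, rss
    if best_spec is None:
        raise ValueError("no admissible FP candidate (collinear designs)")
    return best_spec, best_rss


def select_fp(
    y,
    age,
    sex,
    sites,
    max_degree: int = 3,
    alpha: float = 0.01,
    age_scale: float = DEFAULT_AGE_SCALE,
    include_sex: bool = True,
) -> FPFit:
    """Closed-test selection of the FP degree and powers.

    Implements the standard closed testing sequence, which controls the
    family type-I rate at ~``alpha``: the best FP of the maximum degree M is
    first tested against the age-free model (chi-square LRT, 2M df); only if
    age is needed is it tested against the straight line (partial F, 2M-1
    numerator df), then against the best FP of each lower degree (chi-square
    LRT, 2 df per degree step), stopping at the lowest degree not
    significantly worse than FP(M).  The full trace is stored on the
    returned fit.
    """
    y = np.asarray(y, float)
    age = np.asarray(age, float)
    sites = np.asarray(sites).astype(str)
    n = len(y)
    sexarg = (sex if include_sex else None)

    best: dict[int, tuple[FPSpec, float]] = {}
    for m in range(1, max_degree + 1):
        best[m] = _best_of_degree(y, age, sexarg, m, age_scale)
    lin_spec = FPSpec((1.0,), age_scale)
    _, rss_lin = _fit_ols(y, _design(age, sexarg, lin_spec, n))
    _, rss_null = _fit_ols(y, _design(age, sexarg, FPSpec((), age_scale), n))

    tss = float(np.sum((y - y.mean()) ** 2))
    if min(rss for _, rss in best.values()) <= 1e-12 * max(tss, 1.0) or rss_lin <= 1e-12 * max(tss, 1.0):
        raise ValueError(
            "(near-)zero residual sum of squares: the likelihood-ratio test is "
            "degenerate; add minimal noise jitter to the response"
        )

    def dev(rss: float) -> float:
        return n * np.log(rss / n)

    trace: list[dict] = []
    selected: FPSpec | None = None
    M = max_degree
    spec_top, rss_top = best[M]
    k_top = 1 + (1 if include_sex else 0) + M

    # Gate: best FP(M) vs the age-free model (2 df per degree).
    stat = dev(rss_null) - dev(rss_top)
    p = float(stats.chi2.sf(max(stat, 0.0), df=2 * M))
    trace.append(
        {"comparison": f"FP{M} vs age-free", "statistic": float(stat),
         "df": 2 * M, "p": p, "significant": p < alpha}
    )
    if not p < alpha:
        selected = FPSpec((), age_scale)

    if selected is None:
        # Best FP(M) vs the straight line: partial F, 2M-1 numerator df
        # (the line fixes the power at 1).
        df_num = 2 * M - 1
        F = max(0.0, (rss_lin - rss_top)) / df_num / (rss_top / max(n - k_top, 1))
        p = float(stats.f.sf(F, df_num, max(n - k_top, 1)))
        trace.append(
            {"comparison": f"FP{M} vs line", "statistic": float(F),
             "df": df_num, "p": p, "significant": p < alpha}
        )
        if not p < alpha:
            selected = lin_spec

    if selected is None:
        # Best FP(M) vs best FP(m) for m < M: chi-square LRT with 2 df per
        # degree step; stop at the lowest degree not significantly worse.
        for m in range(1, M):
            stat = dev(best[m][1]) - dev(rss_top)
            df_m = 2 * (M - m)
            p = float(stats.chi2.sf(max(stat, 0.0), df=df_m))
            trace.append(
                {"comparison": f"FP{M} vs FP{m}", "statistic": float(stat),
                 "df": df_m, "p": p, "significant": p < alpha}
            )
            if not p < alpha:
                selected = best[m][0]
                break
        if selected is None:
            selected = spec_top

    fit = fit_fp(y, age, sex, sites, selected, include_sex=include_sex)
    fit.selection_trace = trace
    return fit


def fit_fp_by_sex(y, age, sex, sites, min_n: int = 50, **kwargs) -> dict[str, FPFit | None]:
    """Closed-test FP fits for each sex separately (sex dropped from design)."""
    y = np.asarray(y, float)
    age = np.asarray(age, float)
    sex = np.asarray(sex)
    sites = np.asarray(sites).astype(str)
    out: dict[str, FPFit | None] = {}
    for s in ("M", "F"):
        mask = sex == s
        if mask.sum() < min_n:
            warnings.warn(f"sex {s!r} has {int(mask.sum())} rows (< {min_n}); fit skipped")
            out[s] = None
            continue
        out[s] = select_fp(
            y[mask], age[mask], None, sites[mask], include_sex=False, **kwargs
        )
    return out


def ageband_correlations(
    table: pd.DataFrame,
    region_hemisphere: str,
    bands: tuple[AgeBand, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Pearson correlation between a volume and age within each age band,
    pooled and stratified by sex.  Bands with < 3 rows or zero variance
    report a missing r."""
    rows = []
    ages = table["age"].to_numpy(float)
    for band in bands:
        in_band = band.contains(ages)
        for group in ("all", "M", "F"):
            mask = in_band if group == "all" else in_band & (table["sex"] == group).to_numpy()
            sub_age = ages[mask]
            sub_y = table.loc[mask, region_hemisphere].to_numpy(float)
            r = np.nan
            if len(sub_age) >= 3 and np.ptp(sub_age) > 0 and np.ptp(sub_y) > 0:
                r = float(stats.pearsonr(sub_age, sub_y)[0])
            rows.append(
                {"region_hemisphere": region_hemisphere, "band": band.label,
                 "group": group, "n": int(mask.sum()), "r": r}
            )
    return pd.DataFrame(rows)
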