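"""LMS (Box-Cox Cole-Green) normative centile estimation.

The age-conditional distribution of a positive volume y is modelled by three
parameters: a Box-Cox power lambda (age-constant scalar by default), a
median-type location mu(age) and a coefficient of variation sigma(age).  The
z-score of an observation is

    z = ((y / mu)^lambda - 1) / (lambda * sigma)     (lambda != 0)
    z = ln(y / mu) / sigma                           (lambda  = 0)

and centile curves invert this at standard-normal quantiles.  ln mu and
ln sigma are unpenalized B-spline expansions in age with knots at age
quantiles; for each candidate pair of basis dimensions the likelihood is
maximized by quasi-Newton and the model minimizing GAIC = -2 loglik +
penalty_k * (total degrees of freedom) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline

import pandas as pd

DEFAULT_DF_GRID: tuple[tuple[int, int], ...] = tuple(
    (dm, ds) for dm in (3, 4, 5, 6) for ds in (2, 3, 4)
)
DEFAULT_PENALTY_K = 3.0
DEFAULT_LEVELS: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)

_LAMBDA_EPS = 1e-12


def bccg_z(y, lam, mu, sigma):
    """Box-Cox Cole-Green z-score; continuous in lambda at 0."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(y <= 0) or np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("y, mu and sigma must be positive")
    ratio = np.log(y / mu)
    if abs(lam) < _LAMBDA_EPS:
        z = ratio / sigma
    else:
        z = (np.exp(lam * ratio) - 1.0) / (lam * sigma)
    return float(z) if z.ndim == 0 else z


def bccg_loglik(y, lam, mu, sigma) -> float:
    """Log-likelihood sum(lambda*ln(y/mu) - ln sigma - z^2/2), additive
    constants in the data omitted (the positivity truncation term is also
    omitted, which is negligible for sigma << 1)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float) * np.ones_like(y)
    z = bccg_z(y, lam, mu, sigma)
    return float(np.sum(lam * np.log(y / mu) - np.log(sigma) - 0.5 * z**2))


class _SplineBasis:
    """Unpenalized B-spline basis of a fixed dimension with quantile knots."""

    def __init__(self, x: np.ndarray, df: int):
        if df < 1:
            raise ValueError("df must be >= 1")
        self.df = df
        self.lo = float(np.min(x))
        self.hi = float(np.max(x))
        if df == 1:
            self.degree = 0
            self.knots = None
            return
        self.degree = min(3, df - 1)
        n_interior = df - self.degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        self.knots = np.concatenate(
            [np.repeat(self.lo, self.degree + 1), interior, np.repeat(self.hi, self.degree + 1)]
        )

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.lo, self.hi)
        if self.df == 1:
            return np.ones((len(x), 1))
        # nudge the right endpoint inside the half-open support
        x = np.minimum(x, np.nextafter(self.hi, self.lo))
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "degree": self.degree,
            "knots": None if self.knots is None else self.knots.tolist(),
            "range": [self.lo, self.hi],
        }


@dataclass
class LMSModel:
    """Fitted LMS model: scalar lambda plus log-link spline curves for mu
    (mm^3) and sigma (coefficient of variation)."""

    lam: float
    mu_basis: _SplineBasis
    mu_coef: np.ndarray
    sigma_basis: _SplineBasis
    sigma_coef: np.ndarray
    age_range: tuple[float, float]
    edf: dict[str, float]
    gaic: float
    penalty_k: float
    loglik: float
    converged: bool
    n_iter: int
    grid_trace: list[dict] = field(default_factory=list)

    def mu(self, age) -> np.ndarray:
        return np.exp(self.mu_basis.design(np.atleast_1d(age)) @ self.mu_coef)

    def sigma(self, age) -> np.ndarray:
        return np.exp(self.sigma_basis.design(np.atleast_1d(age)) @ self.sigma_coef)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "mu_basis": self.mu_basis.to_dict(),
            "mu_coef": self.mu_coef.tolist(),
            "sigma_basis": self.sigma_basis.to_dict(),
            "sigma_coef": self.sigma_coef.tolist(),
            "age_range": list(self.age_range),
            "edf": self.edf,
            "gaic": self.gaic,
            "penalty_k": self.penalty_k,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _negloglik(theta: np.ndarray, y, lny, Bmu, Bs) -> float:
    lam = theta[0]
    nm = Bmu.shape[1]
    lnmu = Bmu @ theta[1 : 1 + nm]
    lnsigma = Bs @ theta[1 + nm :]
    if np.any(lnsigma < -15) or np.any(lnsigma > 15) or np.any(np.abs(lnmu) > 50):
        return 1e12
    ratio = lny - lnmu
    sigma = np.exp(lnsigma)
    if abs(lam) < _LAMBDA_EPS:
        z = ratio / sigma
    else:
        z = (np.exp(lam * ratio) - 1.0) / (lam * sigma)
    ll = np.sum(lam * ratio - lnsigma - 0.5 * z**2)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_lms(
    y,
    age,
    df_grid: tuple[tuple[int, int], ...] = DEFAULT_DF_GRID,
    penalty_k: float = DEFAULT_PENALTY_K,
    lambda_bounds: tuple[float, float] = (-3.0, 3.0),
    max_iter: int = 300,
) -> LMSModel:
    """Fit the LMS model over a grid of (df_mu, df_sigma) basis dimensions.

    For each grid entry the likelihood is maximized by L-BFGS-B over
    (lambda, mu spline coefficients, sigma spline coefficients); the model
    minimizing GAIC = -2 loglik + penalty_k * (1 + df_mu + df_sigma) among
    converged candidates is returned, carrying the full grid trace.  With a
    single grid entry the search is skipped and that model returned.
    """
    y = np.asarray(y, float)
    age = np.asarray(age, float)
    if np.any(y <= 0):
        raise ValueError("volumes must be positive")
    if len(y) < 50:
        raise ValueError(f"need >= 50 observations per stratum, got {len(y)}")
    if np.ptp(age) < 20.0 and len(df_grid) > 1:
        raise ValueError("age span must be >= 20 years for smooth curve estimation")

    lny = np.log(y)
    best: LMSModel | None = None
    trace: list[dict] = []
    for df_mu, df_sigma in df_grid:
        mb = _SplineBasis(age, df_mu)
        sb = _SplineBasis(age, df_sigma)
        Bmu = mb.design(age)
        Bs = sb.design(age)

        beta_mu0, *_ = np.linalg.lstsq(Bmu, lny, rcond=None)
        resid = lny - Bmu @ beta_mu0
        s0 = max(float(np.std(resid)), 1e-4)
        beta_s0, *_ = np.linalg.lstsq(Bs, np.full(len(y), np.log(s0)), rcond=None)
        theta0 = np.concatenate([[1.0], beta_mu0, beta_s0])
        bounds = [lambda_bounds] + [(None, None)] * (df_mu + df_sigma)

        res = optimize.minimize(
            _negloglik,
            theta0,
            args=(y, lny, Bmu, Bs),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter},
        )
        ll = -float(res.fun)
        edf_total = 1.0 + df_mu + df_sigma
        gaic = -2.0 * ll + penalty_k * edf_total
        entry = {
            "df_mu": df_mu,
            "df_sigma": df_sigma,
            "loglik": ll,
            "gaic": gaic,
            "converged": bool(res.success),
            "n_iter": int(res.nit),
        }
        trace.append(entry)
        if not np.isfinite(gaic) or (not res.success and len(df_grid) > 1):
            continue
        if best is None or gaic < best.gaic:
            nm = df_mu
            best = LMSModel(
                lam=float(res.x[0]),
                mu_basis=mb,
                mu_coef=res.x[1 : 1 + nm].copy(),
                sigma_basis=sb,
                sigma_coef=res.x[1 + nm :].copy(),
                age_range=(float(np.min(age)), float(np.max(age))),
                edf={"lambda": 1.0, "mu": float(df_mu), "sigma": float(df_sigma)},
                gaic=float(gaic),
                penalty_k=penalty_k,
                loglik=ll,
                converged=bool(res.success),
                n_iter=int(res.nit),
            )
    if best is None:
        raise RuntimeError(f"no LMS candidate converged; grid trace: {trace}")
    best.grid_trace = trace
    return best


def centile_curve(model: LMSModel, ages, level: float, extrapolate: bool = False) -> np.ndarray:
    """Volume at the given centile level (percent) along an age grid."""
    if not 0.0 < level < 100.0:
        raise ValueError("level must lie in (0, 100)")
    ages = np.atleast_1d(np.asarray(ages, float))
    lo, hi = model.age_range
    if not extrapolate and (np.any(ages < lo - 1e-9) or np.any(ages > hi + 1e-9)):
        raise ValueError(f"ages outside the fitted range [{lo}, {hi}]; pass extrapolate=True")
    z = stats.norm.ppf(level / 100.0)
    mu = model.mu(ages)
    sigma = model.sigma(ages)
    if abs(model.lam) < _LAMBDA_EPS:
        return mu * np.exp(sigma * z)
    arg = 1.0 + model.lam * sigma * z
    if np.any(arg <= 0):
        raise ValueError("centile undefined: 1 + lambda*sigma*z <= 0 at some ages")
    return mu * arg ** (1.0 / model.lam)


def centile_of(model: LMSModel, age, y) -> np.ndarray:
    """Centile (percent) of observation(s) y at the given age(s); the inverse
    of :func:`centile_curve` at fixed age."""
    age = np.atleast_1d(np.asarray(age, float))
    y = np.atleast_1d(np.asarray(y, float))
    z = bccg_z(y, model.lam, model.mu(age), model.sigma(age))
    out = np.asarray(stats.norm.cdf(z) * 100.0)
    return out.item() if out.size == 1 else out


def centile_table(
    model: LMSModel,
    ages,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    stratum: dict | None = None,
) -> pd.DataFrame:
    """Tidy table of centile values (one row per age x level)."""
    ages = np.atleast_1d(np.asarray(ages, float))
    rows = []
    for level in levels:
        vals = centile_curve(model, ages, level)
        for a, v in zip(ages, vals):
            row = dict(stratum or {})
            row.update({"age": float(a), "level": float(level), "value": float(v)})
            rows.append(row)
    return pd.DataFrame(rows)
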