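"""Quality control and per-site ICV adjustment.

Stages: complete-case filtering, multivariate outlier exclusion on the 16
region-hemisphere volumes via squared Mahalanobis distance against a
chi-square threshold, and within-site adjustment of each volume for
intracranial volume (ICV) using the analysis-of-covariance formula

    adjusted = raw - b * (ICV - mean ICV)

where ``b`` is the within-site OLS slope of the volume on ICV.  The
adjustment is mean-preserving within site and makes the within-site
volume-on-ICV slope exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VOLUME_COLUMNS

logger = logging.getLogger(__name__)

#: Columns that must be present and non-missing for a complete case.
REQUIRED_COLUMNS = ("age", "sex", "icv") + VOLUME_COLUMNS

#: Ridge added to the covariance diagonal before inverting, as a fraction of
#: the mean diagonal element.
MAHALANOBIS_RIDGE = 1e-6

#: Sites with fewer complete rows than this inherit the pooled ICV slope.
MIN_SITE_N_FOR_SLOPE = 10


@dataclass
class QCReport:
    """Bookkeeping for one QC stage."""

    n_input: int
    n_incomplete_removed: int = 0
    n_outliers_removed: int = 0
    outlier_ids: list[str] = field(default_factory=list)
    mahalanobis_threshold: float | None = None

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_incomplete_removed - self.n_outliers_removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_incomplete_removed": self.n_incomplete_removed,
            "n_outliers_removed": self.n_outliers_removed,
            "n_kept": self.n_kept,
            "outlier_ids": list(self.outlier_ids),
            "mahalanobis_threshold": self.mahalanobis_threshold,
        }


@dataclass(frozen=True)
class ICVAdjustmentModel:
    """Within-site ICV regression for one region-hemisphere volume."""

    site_id: str
    region_hemisphere: str
    b: float
    site_icv_mean: float
    n: int
    pooled_slope: bool = False

    def __post_init__(self) -> None:
        if self.site_icv_mean <= 0:
            raise ValueError("site_icv_mean must be positive")


def filter_complete(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Keep rows with no missing age, sex, ICV or any of the 16 volumes."""
    if len(table) == 0:
        raise ValueError("input table is empty")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks required columns: {missing_cols}")
    mask = table[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    kept = table.loc[mask].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError(
            "all rows are incomplete; check for systematically missing volumes or ICV"
        )
    report = QCReport(n_input=len(table), n_incomplete_removed=int((~mask).sum()))
    return kept, report


def _mahalanobis_d2(x: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distances from the pooled mean, with a small ridge
    on the covariance for numerical stability."""
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    ridge = MAHALANOBIS_RIDGE * np.trace(cov) / cov.shape[0]
    cov_r = cov + ridge * np.eye(cov.shape[0])
    try:
        centered = x - mean
        sol = np.linalg.solve(cov_r, centered.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance in Mahalanobis screening; regularize further "
            "or use fewer columns"
        ) from exc
    return np.einsum("ij,ji->i", centered, sol)


def mahalanobis_exclude(
    table: pd.DataFrame,
    alpha: float = 0.001,
    columns: tuple[str, ...] = VOLUME_COLUMNS,
    per_site: bool = False,
) -> tuple[pd.DataFrame, QCReport]:
    """Exclude multivariate outliers on the volume vector.

    Rows whose squared Mahalanobis distance from the pooled mean/covariance
    exceeds the chi-square(1 - alpha, df = n columns) quantile are removed.
    ``alpha = 0`` disables exclusion (infinite threshold).  With
    ``per_site=True`` distances are computed within each site separately.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    n, k = len(table), len(columns)
    report = QCReport(n_input=n)
    if alpha == 0.0:
        report.mahalanobis_threshold = float("inf")
        return table.reset_index(drop=True), report
    if n <= k:
        raise ValueError(f"need more rows ({n}) than screening columns ({k})")
    threshold = float(stats.chi2.ppf(1.0 - alpha, df=k))
    report.mahalanobis_threshold = threshold

    if per_site:
        d2 = np.empty(n)
        for _, idx in table.groupby("site_id", sort=False).indices.items():
            d2[idx] = _mahalanobis_d2(table.iloc[idx][list(columns)].to_numpy(float))
    else:
        d2 = _mahalanobis_d2(table[list(columns)].to_numpy(float))

    mask = d2 <= threshold
    removed = table.loc[~mask]
    report.n_outliers_removed = int((~mask).sum())
    if "participant_id" in table.columns:
        report.outlier_ids = removed["participant_id"].astype(str).tolist()
    return table.loc[mask].reset_index(drop=True), report


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero ICV variance; slope undefined")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


def fit_icv_adjustment(
    table: pd.DataFrame, site_id: str, region_hemisphere: str
) -> ICVAdjustmentModel:
    """Within-site OLS slope of one volume on ICV plus the site ICV mean."""
    sub = table.loc[table["site_id"] == site_id]
    if len(sub) < 3:
        raise ValueError(
            f"site {site_id!r} has {len(sub)} rows; need >= 3 to fit an ICV slope"
        )
    icv = sub["icv"].to_numpy(float)
    y = sub[region_hemisphere].to_numpy(float)
    return ICVAdjustmentModel(
        site_id=site_id,
        region_hemisphere=region_hemisphere,
        b=_ols_slope(icv, y),
        site_icv_mean=float(icv.mean()),
        n=len(sub),
    )


def apply_icv_adjustment(model: ICVAdjustmentModel, raw, icv):
    """``adjusted = raw - b * (icv - site ICV mean)``."""
    return np.asarray(raw, float) - model.b * (np.asarray(icv, float) - model.site_icv_mean)


def _pooled_slope(table: pd.DataFrame, column: str) -> float:
    """Pooled within-site slope: site-centered OLS across all rows."""
    sxy = sxx = 0.0
    for _, sub in table.groupby("site_id", sort=False):
        x = sub["icv"].to_numpy(float)
        y = sub[column].to_numpy(float)
        sxy += float(np.sum((x - x.mean()) * (y - y.mean())))
        sxx += float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero pooled ICV variance")
    return sxy / sxx


def adjust_icv(
    table: pd.DataFrame, min_site_n: int = MIN_SITE_N_FOR_SLOPE
) -> tuple[pd.DataFrame, list[ICVAdjustmentModel]]:
    """ICV-adjust all 16 volumes per site.

    Sites with fewer than ``min_site_n`` rows inherit the pooled (site-
    centered) slope for each volume, combined with their own ICV mean.
    """
    out = table.copy()
    models: list[ICVAdjustmentModel] = []
    pooled: dict[str, float] = {}
    site_sizes = table.groupby("site_id", sort=False).size()
    if (site_sizes < min_site_n).any():
        pooled = {col: _pooled_slope(table, col) for col in VOLUME_COLUMNS}
        small = site_sizes.index[site_sizes < min_site_n].tolist()
        logger.info("sites %s have < %d rows; using pooled ICV slopes", small, min_site_n)

    for site_id, sub in table.groupby("site_id", sort=False):
        icv = sub["icv"].to_numpy(float)
        icv_mean = float(icv.mean())
        small_site = len(sub) < min_site_n
        for col in VOLUME_COLUMNS:
            if small_site:
                b = pooled[col]
            else:
                b = _ols_slope(icv, sub[col].to_numpy(float))
            model = ICVAdjustmentModel(
                site_id=str(site_id),
                region_hemisphere=col,
                b=b,
                site_icv_mean=icv_mean,
                n=len(sub),
                pooled_slope=small_site,
            )
            models.append(model)
            out.loc[sub.index, col] = apply_icv_adjustment(
                model, sub[col].to_numpy(float), icv
            )
    return out, models
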