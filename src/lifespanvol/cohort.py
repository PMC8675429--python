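"""Multi-site synthetic cohort generator.

Emulates the statistical structure of pooled cross-sectional volumetric MRI
studies: many acquisition sites with heterogeneous sizes and age windows,
additive and multiplicative site effects, a sex effect, coupling of regional
volumes to intracranial volume (ICV), hemisphere-correlated measurement noise,
age-increasing residual spread for selected structures, and a small fraction
of gross outliers.  Ground-truth mean trajectories follow the three archetypes
seen in subcortical aging: an early peak with monotonic decline (basal
ganglia), a flattened inverted U with late-life decline (thalamus,
hippocampus, amygdala), and monotonic enlargement (lateral ventricles).

The default configuration reproduces the site structure of a reference
88-sample, 18,605-participant healthy cohort (ages 3-90) whose descriptors
are bundled as package data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REGIONS: tuple[str, ...] = (
    "lateral_ventricle",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "hippocampus",
    "amygdala",
)
HEMISPHERES: tuple[str, ...] = ("L", "R")
#: Fixed column order of the 16 region-hemisphere volumes in every table.
VOLUME_COLUMNS: tuple[str, ...] = tuple(f"{r}_{h}" for r in REGIONS for h in HEMISPHERES)
ID_COLUMNS: tuple[str, ...] = ("participant_id", "site_id", "age", "sex", "icv")

AGE_MIN, AGE_MAX = 3.0, 90.0

ARCHETYPES = ("early_peak_decline", "inverted_U", "monotonic_increase")

# Ages at which the early-decline archetype peaks and the inverted-U
# archetype reaches its plateau; fixed so trajectories are exactly testable.
_EARLY_PEAK_AGE = 8.0
_PLATEAU_START_AGE = 25.0
# Linear rise per year on the pre-peak limb, as fraction of `level`.
_RISE_FRACTION_DECLINE = 0.01
_RISE_FRACTION_INVU = 0.008

#: Correlation of left/right measurement noise, fixed (hemispheric volumes
#: are strongly correlated empirically).
LR_NOISE_CORRELATION = 0.8


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth mean age trajectory for one structure.

    Parameters
    ----------
    archetype
        One of ``early_peak_decline``, ``inverted_U``, ``monotonic_increase``.
    level
        Volume scale in mm^3: the peak (plateau) value for the declining
        archetypes, the value at age 3 for ``monotonic_increase``.
    decline_rate
        Linear age slope magnitude in mm^3/year: decline after the peak for
        ``early_peak_decline``, increase for ``monotonic_increase``.
    plateau_end
        Age (years) at which the late decline of ``inverted_U`` begins.
    late_rate
        Decline rate (mm^3/year) after ``plateau_end`` (``inverted_U`` only).
    sex_effect
        Additive male-minus-female mean difference in mm^3.
    """

    archetype: str
    level: float
    decline_rate: float = 0.0
    plateau_end: float = 60.0
    late_rate: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}")
        if self.level <= 0:
            raise ValueError("level must be positive")
        if self.archetype == "inverted_U" and not (30.0 < self.plateau_end < 70.0):
            raise ValueError("plateau_end must lie in (30, 70) for inverted_U")
        if self.archetype == "monotonic_increase" and self.decline_rate < 0:
            raise ValueError("monotonic_increase requires a nonnegative rate")


def true_mean(params: TrajectoryParams, age, sex: str | None = None):
    """Ground-truth mean volume (mm^3) at ``age`` for the given sex.

    ``sex`` is ``"M"``, ``"F"`` or ``None`` for the cross-sex reference level.
    Accepts scalar or array ``age``; the curve is continuous and piecewise
    polynomial: the inverted-U archetype is exactly flat between the early
    peak and ``plateau_end`` and strictly declining after it.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < AGE_MIN) or np.any(age > AGE_MAX):
        raise ValueError(f"age must lie within [{AGE_MIN}, {AGE_MAX}]")
    a = params.archetype
    if a == "early_peak_decline":
        rise = params.level * (1.0 - _RISE_FRACTION_DECLINE * (_EARLY_PEAK_AGE - age))
        fall = params.level - params.decline_rate * (age - _EARLY_PEAK_AGE)
        mu = np.where(age < _EARLY_PEAK_AGE, rise, fall)
    elif a == "inverted_U":
        rise = params.level * (1.0 - _RISE_FRACTION_INVU * (_PLATEAU_START_AGE - age))
        fall = params.level - params.late_rate * (age - params.plateau_end)
        mu = np.where(
            age < _PLATEAU_START_AGE, rise, np.where(age <= params.plateau_end, params.level, fall)
        )
    else:  # monotonic_increase
        mu = params.level + params.decline_rate * (age - AGE_MIN)
    if sex is not None:
        if sex not in ("M", "F"):
            raise ValueError("sex must be 'M', 'F' or None")
        mu = mu + (0.5 if sex == "M" else -0.5) * params.sex_effect
    return float(mu) if mu.ndim == 0 else mu


def default_trajectories() -> dict[str, TrajectoryParams]:
    """Ground-truth trajectories for the 8 structures (mm^3 scales typical of
    adult FreeSurfer segmentations)."""
    return {
        "lateral_ventricle": TrajectoryParams("monotonic_increase", level=5000.0, decline_rate=110.0, sex_effect=900.0),
        "thalamus": TrajectoryParams("inverted_U", level=7700.0, plateau_end=55.0, late_rate=28.0, sex_effect=350.0),
        "caudate": TrajectoryParams("early_peak_decline", level=3900.0, decline_rate=6.0, sex_effect=180.0),
        "putamen": TrajectoryParams("early_peak_decline", level=5500.0, decline_rate=12.0, sex_effect=300.0),
        "pallidum": TrajectoryParams("early_peak_decline", level=1800.0, decline_rate=3.0, sex_effect=100.0),
        "accumbens": TrajectoryParams("early_peak_decline", level=650.0, decline_rate=1.6, sex_effect=40.0),
        "hippocampus": TrajectoryParams("inverted_U", level=4300.0, plateau_end=58.0, late_rate=22.0, sex_effect=200.0),
        "amygdala": TrajectoryParams("inverted_U", level=1700.0, plateau_end=60.0, late_rate=7.0, sex_effect=120.0),
    }


#: Baseline measurement-noise SD per region (mm^3); ventricles are by far the
#: most dispersed structure relative to their mean.
DEFAULT_NOISE_SD: dict[str, float] = {
    "lateral_ventricle": 1600.0,
    "thalamus": 650.0,
    "caudate": 420.0,
    "putamen": 550.0,
    "pallidum": 200.0,
    "accumbens": 95.0,
    "hippocampus": 420.0,
    "amygdala": 180.0,
}

DEFAULT_HETEROSCEDASTIC_REGIONS = frozenset({"lateral_ventricle", "hippocampus", "amygdala"})

#: Linear growth of noise SD with age (mm^3/year) for heteroscedastic regions.
DEFAULT_HETERO_SLOPE: dict[str, float] = {
    "lateral_ventricle": 28.0,
    "hippocampus": 6.0,
    "amygdala": 2.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the multi-site cohort simulator.

    ``noise_sd_base`` and ``hetero_slope`` may be a single value in mm^3
    (applied to every region) or a mapping region -> value; regional volume
    scales span an order of magnitude, so the defaults are per-region.
    """

    n_sites: int
    site_sizes: tuple[int, ...]
    site_age_ranges: tuple[tuple[float, float], ...]
    sex_ratio: float = 0.48
    site_shift_sd: float = 150.0
    site_scale_range: tuple[float, float] = (0.9, 1.1)
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    icv_slope_b: float = 0.002
    noise_sd_base: float | Mapping[str, float] | None = None
    heteroscedastic_regions: frozenset[str] = DEFAULT_HETEROSCEDASTIC_REGIONS
    hetero_slope: float | Mapping[str, float] | None = None
    outlier_rate: float = 0.0
    outlier_scale: float = 6.0
    seed: int = 0
    # Optional per-site refinements (None -> uniform ages, global sex ratio).
    site_age_means: tuple[float, ...] | None = None
    site_age_sds: tuple[float, ...] | None = None
    site_sex_ratios: tuple[float, ...] | None = None
    site_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        for name in ("site_sizes", "site_age_ranges"):
            if len(getattr(self, name)) != self.n_sites:
                raise ValueError(f"{name} must have length n_sites={self.n_sites}")
        for opt in ("site_age_means", "site_age_sds", "site_sex_ratios", "site_ids"):
            val = getattr(self, opt)
            if val is not None and len(val) != self.n_sites:
                raise ValueError(f"{opt} must have length n_sites={self.n_sites}")
        if any(s <= 0 for s in self.site_sizes):
            raise ValueError("site_sizes must be positive")
        for lo, hi in self.site_age_ranges:
            if not (AGE_MIN <= lo <= hi <= AGE_MAX):
                raise ValueError(f"age interval [{lo}, {hi}] must lie within [{AGE_MIN}, {AGE_MAX}]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.site_shift_sd < 0 or self.icv_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        lo, hi = self.site_scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("site_scale_range must satisfy 0 < lo <= hi")
        if self.icv_mean <= 0:
            raise ValueError("icv_mean must be positive")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.outlier_rate > 0 and self.outlier_scale < 3.0:
            raise ValueError("outlier_scale must be >= 3 when outliers are generated")
        for val in self._noise_map().values():
            if val < 0:
                raise ValueError("noise SDs must be nonnegative")

    def _as_region_map(self, value, defaults: Mapping[str, float]) -> dict[str, float]:
        if value is None:
            return dict(defaults)
        if isinstance(value, Mapping):
            return {r: float(value.get(r, 0.0)) for r in REGIONS}
        return {r: float(value) for r in REGIONS}

    def _noise_map(self) -> dict[str, float]:
        return self._as_region_map(self.noise_sd_base, DEFAULT_NOISE_SD)

    def _hetero_map(self) -> dict[str, float]:
        full = self._as_region_map(self.hetero_slope, DEFAULT_HETERO_SLOPE)
        return {r: (full[r] if r in self.heteroscedastic_regions else 0.0) for r in REGIONS}


def load_site_descriptors() -> pd.DataFrame:
    """Bundled descriptors of the 88-sample reference cohort: per-sample age
    mean/SD/range, size, and male/female counts."""
    with importlib.resources.files("lifespanvol.data").joinpath("site_descriptors.csv").open() as fh:
        return pd.read_csv(fh)


def default_sim_config(scale: float = 1.0, seed: int = 0, **overrides) -> SimConfig:
    """SimConfig mirroring the bundled 88-site reference cohort.

    ``scale`` multiplies every site size (minimum 5 per site), allowing
    smaller but structurally identical cohorts. Keyword overrides replace any
    SimConfig field.
    """
    desc = load_site_descriptors()
    sizes = tuple(int(max(5, round(n * scale))) for n in desc["n"])
    cfg = SimConfig(
        n_sites=len(desc),
        site_sizes=sizes,
        site_age_ranges=tuple(
            (max(AGE_MIN, float(lo)), min(AGE_MAX, float(hi)))
            for lo, hi in zip(desc["age_lo"], desc["age_hi"])
        ),
        sex_ratio=float(desc["n_male"].sum() / desc["n"].sum()),
        site_age_means=tuple(float(v) for v in desc["age_mean"]),
        site_age_sds=tuple(float(v) for v in desc["age_sd"]),
        site_sex_ratios=tuple(float(m) / float(n) for m, n in zip(desc["n_male"], desc["n"])),
        site_ids=tuple(desc["sample"]),
        outlier_rate=0.003,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _sample_ages(rng: np.random.Generator, n: int, lo: float, hi: float,
                 mean: float | None, sd: float | None) -> np.ndarray:
    if mean is None or sd is None or sd <= 0 or lo == hi:
        return rng.uniform(lo, hi, size=n)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    config: SimConfig, trajectories: Mapping[str, TrajectoryParams] | None = None
) -> pd.DataFrame:
    """Simulate a multi-site cohort table.

    The observed volume of region r, hemisphere h for a participant at site i
    is ``delta_ir * (mu_r(age, sex) + b * (ICV - icv_mean) + noise_rh) +
    gamma_ir`` with ``gamma_ir ~ N(0, site_shift_sd^2)`` and ``delta_ir``
    uniform on ``site_scale_range`` (both drawn per site and region).  Noise
    is Gaussian with left/right correlation 0.8 and, for heteroscedastic
    regions, SD growing linearly in age.  A fraction ``outlier_rate`` of rows
    is displaced by ``outlier_scale`` noise SDs in every volume.

    Deterministic given ``config`` (including its seed).
    """
    if trajectories is None:
        trajectories = default_trajectories()
    missing = [r for r in REGIONS if r not in trajectories]
    if missing:
        raise ValueError(f"trajectories missing regions: {missing}")
    if sum(config.site_sizes) == 0:
        raise ValueError("total cohort size is zero")

    rng = np.random.default_rng(config.seed)
    noise_map = config._noise_map()
    hetero_map = config._hetero_map()

    frames: list[pd.DataFrame] = []
    pid = 0
    for i in range(config.n_sites):
        n = config.site_sizes[i]
        lo, hi = config.site_age_ranges[i]
        site_id = config.site_ids[i] if config.site_ids is not None else f"site_{i:03d}"
        mean = config.site_age_means[i] if config.site_age_means is not None else None
        sd = config.site_age_sds[i] if config.site_age_sds is not None else None
        ratio = config.site_sex_ratios[i] if config.site_sex_ratios is not None else config.sex_ratio

        ages = _sample_ages(rng, n, lo, hi, mean, sd)
        sexes = np.where(rng.random(n) < ratio, "M", "F")
        icv = rng.normal(config.icv_mean, config.icv_sd, size=n)
        icv = np.clip(icv, 0.2 * config.icv_mean, None)  # ICV strictly positive

        cols: dict[str, np.ndarray] = {
            "participant_id": np.array([f"P{pid + j:06d}" for j in range(n)]),
            "site_id": np.repeat(site_id, n),
            "age": ages,
            "sex": sexes,
            "icv": icv,
        }
        pid += n

        sexsign = np.where(sexes == "M", 0.5, -0.5)
        icv_term = config.icv_slope_b * (icv - config.icv_mean)
        for region in REGIONS:
            params = trajectories[region]
            gamma = rng.normal(0.0, config.site_shift_sd)
            delta = rng.uniform(*config.site_scale_range)
            mu = true_mean(params, ages) + sexsign * params.sex_effect
            sd_noise = noise_map[region] + hetero_map[region] * (ages - AGE_MIN)
            e1 = rng.standard_normal(n)
            e2 = rng.standard_normal(n)
            rho = LR_NOISE_CORRELATION
            noise_l = sd_noise * e1
            noise_r = sd_noise * (rho * e1 + np.sqrt(1.0 - rho**2) * e2)
            cols[f"{region}_L"] = delta * (mu + icv_term + noise_l) + gamma
            cols[f"{region}_R"] = delta * (mu + icv_term + noise_r) + gamma
        frames.append(pd.DataFrame(cols))

    table = pd.concat(frames, ignore_index=True)

    if config.outlier_rate > 0:
        n_total = len(table)
        n_out = int(round(config.outlier_rate * n_total))
        if n_out > 0:
            idx = rng.choice(n_total, size=n_out, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_out)
            ages_out = table["age"].to_numpy()[idx]
            for region in REGIONS:
                sd_noise = noise_map[region] + hetero_map[region] * (ages_out - AGE_MIN)
                shift = signs * config.outlier_scale * sd_noise
                for h in HEMISPHERES:
                    col = f"{region}_{h}"
                    vals = table[col].to_numpy()
                    vals[idx] = vals[idx] + shift
                    table[col] = vals

    return table[list(ID_COLUMNS) + list(VOLUME_COLUMNS)]
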