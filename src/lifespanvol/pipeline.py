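"""End-to-end orchestration: schema-validated I/O, configuration, and the
stage sequence QC -> ICV adjustment -> site harmonization -> trajectory
selection -> variability -> centiles, with a manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    ID_COLUMNS,
    VOLUME_COLUMNS,
    default_sim_config,
    default_trajectories,
    generate_cohort,
)
from .combat import harmonize_table
from .fracpoly import (
    DEFAULT_BANDS,
    FPFit,
    ageband_correlations,
    fit_fp_by_sex,
    select_fp,
)
from .lms import DEFAULT_LEVELS, LMSModel, centile_table, fit_lms
from .preprocess import adjust_icv, filter_complete, mahalanobis_exclude
from .variability import (
    bonferroni_threshold,
    meta_sd,
    variability_by_band_meta,
    variance_report,
)

logger = logging.getLogger(__name__)

EXPECTED_COLUMNS = tuple(ID_COLUMNS) + tuple(VOLUME_COLUMNS)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table (comma-separated, UTF-8, header).

    Checks the column set, the sex domain (M/F, empty allowed for later
    complete-case filtering) and that ages parse as numbers within 3-90;
    offending rows are named in the error.
    """
    table = pd.read_csv(
        path, dtype={"participant_id": str, "site_id": str}, skipinitialspace=True
    )
    unknown = [c for c in table.columns if c not in EXPECTED_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    missing = [c for c in EXPECTED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    ages = pd.to_numeric(table["age"], errors="coerce")
    bad_age = table.index[table["age"].notna() & ages.isna()].tolist()
    if bad_age:
        raise ValueError(f"non-numeric ages at rows {bad_age[:10]}")
    out_of_range = table.index[(ages < 3.0) | (ages > 90.0)].tolist()
    if out_of_range:
        raise ValueError(f"ages outside [3, 90] at rows {out_of_range[:10]}")
    table["age"] = ages

    sex = table["sex"].astype("string").str.strip()
    bad_sex = table.index[sex.notna() & ~sex.isin(["M", "F"])].tolist()
    if bad_sex:
        raise ValueError(f"invalid sex values at rows {bad_sex[:10]}")
    table["sex"] = sex

    for col in ("icv",) + tuple(VOLUME_COLUMNS):
        table[col] = pd.to_numeric(table[col], errors="raise")
    neg_icv = table.index[table["icv"].notna() & (table["icv"] <= 0)].tolist()
    if neg_icv:
        raise ValueError(f"nonpositive ICV at rows {neg_icv[:10]}")
    logger.info("read %d rows from %s", len(table), path)
    return table[list(EXPECTED_COLUMNS)]


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical column order; missing values as
    empty fields."""
    table[list(EXPECTED_COLUMNS)].to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serializable to/from YAML."""

    input_path: str | None = None  # None -> simulate the bundled default cohort
    output_dir: str | None = None
    seed: int = 0
    sim_scale: float = 0.65  # bundled cohort ~12,000 rows at the default
    icv_adjust: bool = True
    mahalanobis_alpha: float = 0.001
    combat_age_degree: int = 3
    combat_per_hemisphere: bool = False
    fp_alpha: float = 0.01
    fp_max_degree: int = 3
    fp_age_scale: float = 10.0
    family_alpha: float = 0.05
    variance_method: str = "brown-forsythe"
    centile_levels: tuple[float, ...] = DEFAULT_LEVELS
    lms_df_mu: tuple[int, ...] = (3, 4, 5, 6)
    lms_df_sigma: tuple[int, ...] = (2, 3, 4)
    lms_penalty_k: float = 3.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("centile_levels", "lms_df_mu", "lms_df_sigma"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("centile_levels", "lms_df_mu", "lms_df_sigma"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    config: PipelineConfig
    cohort_raw: pd.DataFrame
    cohort: pd.DataFrame  # QC'd, ICV-adjusted, harmonized
    qc: dict
    icv_models: list
    combat_model: object
    fp_fits: dict[str, FPFit]
    fp_by_sex: dict[str, dict]
    band_correlations: pd.DataFrame
    variance_reports: list
    meta_overall: dict
    meta_by_band: dict
    centile_models: dict[tuple[str, str], LMSModel]
    centile_tables: pd.DataFrame
    manifest: dict


def _residuals(fit: FPFit, y: np.ndarray, age: np.ndarray, sexes) -> np.ndarray:
    n = len(y)
    cols = [np.ones(n)]
    if fit.include_sex:
        cols.append(np.where(np.asarray(sexes) == "M", 0.5, -0.5))
    from .fracpoly import fp_basis

    basis = fp_basis(age / fit.spec.age_scale, fit.spec.powers)
    for j in range(basis.shape[1]):
        cols.append(basis[:, j])
    return y - np.column_stack(cols) @ fit.coefficients


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stage
    order.  Deterministic given (config, seed): identical configurations
    regenerate identical artefacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str, writer) -> None:
        if outdir:
            writer(outdir / name)
            outputs.append(name)

    # --- input ---------------------------------------------------------
    if config.input_path:
        cohort_raw = read_cohort(config.input_path)
    else:
        sim = default_sim_config(scale=config.sim_scale, seed=config.seed)
        cohort_raw = generate_cohort(sim, default_trajectories())
        logger.info("simulated %d rows across %d sites", len(cohort_raw), sim.n_sites)
        emit("cohort_raw.csv", lambda p: write_cohort(cohort_raw, p))

    # --- QC ------------------------------------------------------------
    table, rep_complete = filter_complete(cohort_raw)
    table, rep_outlier = mahalanobis_exclude(table, alpha=config.mahalanobis_alpha)
    qc = {
        "complete_cases": rep_complete.to_dict(),
        "mahalanobis": rep_outlier.to_dict(),
    }
    emit("qc_report.json", lambda p: p.write_text(json.dumps(qc, indent=2)))

    # --- ICV adjustment -------------------------------------------------
    if config.icv_adjust:
        table, icv_models = adjust_icv(table)
        emit(
            "icv_models.json",
            lambda p: p.write_text(
                json.dumps([dataclasses.asdict(m) for m in icv_models], indent=2)
            ),
        )
    else:
        icv_models = []
        logger.info("ICV adjustment bypassed (sensitivity path); outputs are ICV-unadjusted")

    # --- harmonization --------------------------------------------------
    table, combat_model = harmonize_table(
        table,
        per_hemisphere=config.combat_per_hemisphere,
        age_degree=config.combat_age_degree,
    )
    emit("cohort_harmonized.csv", lambda p: write_cohort(table, p))
    if outdir and not isinstance(combat_model, list):
        emit("combat_model.json", lambda p: combat_model.to_json(p))

    ages = table["age"].to_numpy(float)
    sexes = table["sex"].to_numpy()
    sites = table["site_id"].to_numpy()

    # --- trajectories ----------------------------------------------------
    fp_fits: dict[str, FPFit] = {}
    fp_by_sex: dict[str, dict] = {}
    corr_frames = []
    curve_rows = []
    age_grid = np.arange(3.0, 90.0 + 1e-9, 0.5)
    for col in VOLUME_COLUMNS:
        y = table[col].to_numpy(float)
        fit = select_fp(
            y, ages, sexes, sites,
            max_degree=config.fp_max_degree, alpha=config.fp_alpha,
            age_scale=config.fp_age_scale,
        )
        fp_fits[col] = fit
        fp_by_sex[col] = fit_fp_by_sex(
            y, ages, sexes, sites,
            max_degree=config.fp_max_degree, alpha=config.fp_alpha,
            age_scale=config.fp_age_scale,
        )
        corr_frames.append(ageband_correlations(table, col))
        for sex_label, sex_arg in (("all", None), ("M", "M"), ("F", "F")):
            pred = fit.predict(age_grid, sex_arg)
            curve_rows.append(
                pd.DataFrame(
                    {"region_hemisphere": col, "sex": sex_label, "age": age_grid,
                     "fitted": pred}
                )
            )
    band_correlations = pd.concat(corr_frames, ignore_index=True)
    emit(
        "fp_fits.json",
        lambda p: p.write_text(
            json.dumps({c: f.to_dict() for c, f in fp_fits.items()}, indent=2)
        ),
    )
    emit(
        "fp_curves.csv",
        lambda p: pd.concat(curve_rows, ignore_index=True).to_csv(p, index=False),
    )
    emit("ageband_correlations.csv", lambda p: band_correlations.to_csv(p, index=False))

    # --- variability ------------------------------------------------------
    corrected_alpha = bonferroni_threshold(config.family_alpha, len(VOLUME_COLUMNS))
    variance_reports = []
    meta_overall = {}
    meta_by_band = {}
    for col in VOLUME_COLUMNS:
        y = table[col].to_numpy(float)
        resid = _residuals(fp_fits[col], y, ages, sexes)
        variance_reports.append(
            variance_report(
                resid, ages, col,
                corrected_alpha=corrected_alpha, method=config.variance_method,
            )
        )
        site_stats = table.groupby("site_id")[col].agg(["std", "count"]).dropna()
        usable = site_stats[(site_stats["count"] >= 2) & (site_stats["std"] > 0)]
        meta_overall[col] = meta_sd(
            usable["std"].to_numpy(), usable["count"].to_numpy(), usable.index.to_numpy()
        )
        meta_by_band[col] = variability_by_band_meta(table, col)
    emit(
        "variance_reports.json",
        lambda p: p.write_text(
            json.dumps([r.to_dict() for r in variance_reports], indent=2)
        ),
    )
    emit(
        "meta_sd.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    col: {
                        "overall": meta_overall[col].to_dict(),
                        "by_band": {b: m.to_dict() for b, m in meta_by_band[col].items()},
                    }
                    for col in VOLUME_COLUMNS
                },
                indent=2,
            )
        ),
    )

    # --- centiles ---------------------------------------------------------
    df_grid = tuple((dm, ds) for dm in config.lms_df_mu for ds in config.lms_df_sigma)
    centile_models: dict[tuple[str, str], LMSModel] = {}
    centile_frames = []
    for col in VOLUME_COLUMNS:
        for sex_label in ("M", "F"):
            mask = (sexes == sex_label) & (table[col].to_numpy(float) > 0)
            n_dropped = int(((sexes == sex_label) & ~mask).sum())
            if n_dropped:
                logger.info("%s/%s: dropped %d nonpositive volumes before LMS", col, sex_label, n_dropped)
            y = table.loc[mask, col].to_numpy(float)
            a = ages[mask]
            model = fit_lms(
                y, a, df_grid=df_grid, penalty_k=config.lms_penalty_k
            )
            centile_models[(col, sex_label)] = model
            grid = np.arange(
                np.ceil(model.age_range[0]), np.floor(model.age_range[1]) + 1e-9, 1.0
            )
            region, hemi = col.rsplit("_", 1)
            centile_frames.append(
                centile_table(
                    model, grid, levels=config.centile_levels,
                    stratum={"region": region, "hemisphere": hemi, "sex": sex_label},
                )
            )
    centile_tables = pd.concat(centile_frames, ignore_index=True)
    emit("centiles.csv", lambda p: centile_tables.to_csv(p, index=False))
    emit(
        "centile_models.json",
        lambda p: p.write_text(
            json.dumps(
                {f"{c}|{s}": m.to_dict() for (c, s), m in centile_models.items()},
                indent=2,
            )
        ),
    )

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "icv_adjusted": config.icv_adjust,
        "n_rows_analyzed": int(len(table)),
        "n_fp_fits": len(fp_fits),
        "n_variance_reports": len(variance_reports),
        "n_centile_tables": len(centile_models),
        "corrected_alpha": corrected_alpha,
        "outputs": outputs,
        "qc": qc,
    }
    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        cohort_raw=cohort_raw,
        cohort=table,
        qc=qc,
        icv_models=icv_models,
        combat_model=combat_model,
        fp_fits=fp_fits,
        fp_by_sex=fp_by_sex,
        band_correlations=band_correlations,
        variance_reports=variance_reports,
        meta_overall=meta_overall,
        meta_by_band=meta_by_band,
        centile_models=centile_models,
        centile_tables=centile_tables,
        manifest=manifest,
    )
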