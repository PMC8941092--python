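"""End-to-end orchestration: ingest or simulate a fire record, then run
interval statistics, the null model, trend estimates, cover-type trends and
the predictability analysis from one configuration, with a reproducibility
manifest.

One master seed expands deterministically into per-stage seeds (simulation,
null model, trend bootstrap, random forest) drawn in a fixed order from a
generator seeded with the master, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cover as cover_mod
from . import fire_history as fh
from . import null_model as nm
from . import reburn_stats as rs
from . import rf as rf_mod
from . import synthetic as syn
from . import trends as tr

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("simulate", "null_model", "trends", "rf")


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    mode: str = "synthetic"  # "synthetic" | "rasters"
    raster_dir: str | None = None
    covariates: str | None = None
    cover_mapping: str | None = None
    grid_shape: tuple[int, int] = (100, 100)
    cell_size: float = 1000.0
    years: tuple[int, ...] = tuple(range(1984, 2017))
    burn_fraction: Any = None
    n_fires_per_year: int = 16
    refractory_tau: int = 10
    refractory_rho: float = 0.1
    spacing: float = 1000.0
    threshold: int = 2
    windows: tuple[int, ...] = (10, 20)
    max_interval: int = 16
    null_reps: int = 10_000
    bootstrap_reps: int = 2_000
    rf_enabled: bool = True
    rf_forests: int = 20
    rf_trees: int = 500
    rf_alpha: float = 0.05
    min_class_size: int = 25
    seed: int = 0

    _KNOWN = None  # filled after class creation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        for key in ("years", "windows"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d.get("burn_fraction"), np.ndarray):
            d["burn_fraction"] = d["burn_fraction"].tolist()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """All constraint violations (empty list iff runnable)."""
    v: list[str] = []
    if config.mode not in ("synthetic", "rasters"):
        v.append(f"mode: must be 'synthetic' or 'rasters', got {config.mode!r}")
    if config.mode == "rasters":
        if not config.raster_dir:
            v.append("raster_dir: required in rasters mode")
        elif not Path(config.raster_dir).is_dir():
            v.append(f"raster_dir: {config.raster_dir} does not exist")
        if config.covariates and not Path(config.covariates).is_file():
            v.append(f"covariates: {config.covariates} does not exist")
    if config.cover_mapping and not Path(config.cover_mapping).is_file():
        v.append(f"cover_mapping: {config.cover_mapping} does not exist")
    if config.null_reps < 1:
        v.append("null_reps: must be >= 1")
    if config.bootstrap_reps < 1:
        v.append("bootstrap_reps: must be >= 1")
    if config.spacing <= 0:
        v.append("spacing: must be positive")
    if config.threshold < 0:
        v.append("threshold: must be >= 0")
    n_years = len(config.years)
    for w in config.windows:
        if w < 1:
            v.append(f"windows: window {w} must be >= 1")
        elif w >= n_years:
            v.append(
                f"windows: window {w} does not fit a {n_years}-year record"
            )
    if not 0 <= config.refractory_rho <= 1:
        v.append("refractory_rho: must be in [0, 1]")
    if config.refractory_tau < 0:
        v.append("refractory_tau: must be >= 0")
    return v


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seeds: dict[str, int]
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def stage_seeds(master_seed: int) -> dict[str, int]:
    rng = np.random.default_rng(master_seed)
    draws = rng.integers(0, 2**31 - 1, size=len(_STAGE_ORDER))
    return {name: int(s) for name, s in zip(_STAGE_ORDER, draws)}


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute all stages in dependency order, writing per-stage outputs and
    a manifest sufficient to re-run bit-identically."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        stage_seeds=seeds,
    )

    # --- ingest / simulate -------------------------------------------------
    if config.mode == "synthetic":
        sim = syn.SimConfig(
            grid_shape=config.grid_shape,
            cell_size=config.cell_size,
            years=config.years,
            burn_fraction=config.burn_fraction,
            n_fires_per_year=config.n_fires_per_year,
            refractory_tau=config.refractory_tau,
            refractory_rho=config.refractory_rho,
            seed=seeds["simulate"],
        )
        landscape = syn.make_landscape(sim)
        syn.simulate_fire_history(landscape)
        data_dir = outdir / "data"
        syn.write_history(landscape, data_dir, spacing=config.spacing)
        raster_dir, cov_path = data_dir, data_dir / "covariates.csv"
    else:
        raster_dir = Path(config.raster_dir)
        cov_path = Path(config.covariates) if config.covariates else None

    stack = fh.read_severity_stack(raster_dir)
    points = fh.sample_point_grid(stack.extent, config.spacing)
    if cov_path is not None:
        cov_table = pd.read_csv(cov_path)
        points = fh.attach_covariates(points, cov_table)
    histories = fh.extract_burn_histories(stack, points, config.threshold)
    fh.write_histories(histories, outdir / "histories.csv", points)
    manifest.stages["ingest"] = {
        "n_points": len(points),
        "n_years": len(stack.years),
        "outputs": ["histories.csv"],
    }

    # --- interval statistics ----------------------------------------------
    strata = None
    if points.covariates is not None and "ecoregion" in points.covariates:
        strata = points.covariates["ecoregion"].to_dict()
    summaries = rs.burn_count_summary(histories, strata)
    rs.summary_frame(summaries).to_csv(outdir / "burn_summary.csv", index=False)
    intervals = rs.fire_intervals(histories)
    intervals.to_csv(outdir / "intervals.csv", index=False)
    tails: dict[str, float] = {}
    if len(intervals):
        ecdf = rs.interval_ecdf(intervals, config.max_interval)
        ecdf.table.to_csv(outdir / "ecdf.csv", index=False)
        tails = {
            str(k): v for k, v in rs.interval_tail_fractions(intervals, [5, 10]).items()
        }
    (outdir / "tail_fractions.json").write_text(
        json.dumps(tails, indent=2, sort_keys=True)
    )
    manifest.stages["intervals"] = {
        "n_intervals": int(len(intervals)),
        "outputs": ["burn_summary.csv", "intervals.csv", "ecdf.csv",
                    "tail_fractions.json"],
    }

    # --- null model + trends ----------------------------------------------
    trend_report: dict[str, dict] = {}
    for w in config.windows:
        series = nm.window_series(
            histories, w, stack.years, reps=config.null_reps,
            seed=seeds["null_model"] + w,
        )
        series.to_csv(outdir / f"null_w{w}.csv", index=False)
        obs = series.dropna(subset=["observed"])
        entry: dict[str, Any] = {"n_years": int(len(obs))}
        for col, label in (("observed", "observed"), ("null_mean", "null")):
            y = obs[col].to_numpy()
            if len(obs) >= 3 and np.ptp(y) > 0:
                est = tr.theil_sen(
                    obs["focal_year"].to_numpy(), y,
                    bootstrap_reps=config.bootstrap_reps,
                    seed=seeds["trends"] + w,
                )
                bp = tr.box_pierce(y)
                entry[label] = est.as_dict() | {
                    "box_pierce": {"Q": bp.Q, "lags": bp.lags, "p": bp.p_value}
                }
            else:
                entry[label] = None
        trend_report[f"W{w}"] = entry
    if len(config.windows) >= 2:
        lo, hi = sorted(config.windows)[:2]
        band = nm.interval_band_series(
            histories, lo, hi, stack.years, reps=config.null_reps,
            seed=seeds["null_model"],
        )
        band.to_csv(outdir / f"band_{lo}_{hi}.csv", index=False)
    (outdir / "trends.json").write_text(
        json.dumps(trend_report, indent=2, sort_keys=True, default=float)
    )
    manifest.stages["null_model"] = {
        "windows": list(config.windows),
        "reps": config.null_reps,
        "outputs": [f"null_w{w}.csv" for w in config.windows] + ["trends.json"],
    }

    # --- cover-type trends --------------------------------------------------
    if points.covariates is not None and "cover" in points.covariates:
        mapping = (
            cover_mod.load_mapping(config.cover_mapping)
            if config.cover_mapping
            else cover_mod.DEFAULT_LANDCOVER_MAPPING
        )
        cover_map = {
            int(pid): cover_mod.collapse_landcover(raw, mapping)
            for pid, raw in points.covariates["cover"].items()
        }
        cover_report = {}
        for w in config.windows:
            tables = cover_mod.cover_reburn_proportions(
                histories, cover_map, w, stack.years
            )
            tables.to_csv(outdir / f"cover_w{w}.csv", index=False)
            try:
                est = cover_mod.conifer_trend(tables)
                cover_report[f"W{w}"] = est.as_dict()
            except ValueError as err:
                logger.warning("conifer trend W=%d not estimable: %s", w, err)
                cover_report[f"W{w}"] = None
        (outdir / "conifer_trend.json").write_text(
            json.dumps(cover_report, indent=2, sort_keys=True, default=float)
        )
        manifest.stages["cover"] = {
            "outputs": [f"cover_w{w}.csv" for w in config.windows]
            + ["conifer_trend.json"],
        }

    # --- predictability (random forest) -------------------------------------
    if config.rf_enabled and points.covariates is not None:
        table = _feature_table(histories, points)
        if table is not None and (
            table[rf_mod.LABEL_COL].value_counts().min() >= config.min_class_size
        ):
            result = rf_mod.run_importance_forests(
                table,
                n_forests=config.rf_forests,
                n_trees=config.rf_trees,
                alpha=config.rf_alpha,
                seed=seeds["rf"],
            )
            result.importances.to_csv(outdir / "importance.csv", index=False)
            report = rf_mod.importance_report(result)
            report.to_csv(outdir / "importance_report.csv")
            (outdir / "rf.json").write_text(
                json.dumps(
                    {
                        "test_accuracy_mean": float(result.test_accuracy.mean()),
                        "test_accuracy_min": float(result.test_accuracy.min()),
                        "test_accuracy_max": float(result.test_accuracy.max()),
                        "n_forests": result.n_forests,
                        "n_trees": result.n_trees,
                        "n_rows": int(len(table)),
                    },
                    indent=2, sort_keys=True,
                )
            )
            manifest.stages["rf"] = {
                "n_rows": int(len(table)),
                "outputs": ["importance.csv", "importance_report.csv", "rf.json"],
            }
        else:
            logger.warning(
                "too few points per class for the predictability stage; skipped"
            )
            manifest.stages["rf"] = {"skipped": "insufficient class sizes"}

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _feature_table(histories, points) -> pd.DataFrame | None:
    """Single-fire vs reburn feature matrix from burned points' covariates."""
    cov = points.covariates
    numeric = [
        c for c in cov.columns
        if c not in ("ecoregion", "cover") and pd.api.types.is_numeric_dtype(cov[c])
    ]
    if not numeric:
        return None
    n_burns = {h.point_id: h.n_burns for h in histories}
    ids = [pid for pid in cov.index if n_burns.get(int(pid), 0) >= 1]
    if not ids:
        return None
    table = cov.loc[ids, numeric].copy()
    if "aspect" in table:
        table["aspect"] = rf_mod.transform_aspect(table["aspect"].to_numpy())
    table[rf_mod.LABEL_COL] = [2 if n_burns[int(p)] >= 2 else 1 for p in ids]
    return table
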