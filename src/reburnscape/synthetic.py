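"""Synthetic boreal fire-landscape generator.

Emulates the statistical structure the reburn analysis assumes: ~30 annual
burn masks with year-varying burned fractions, spatially clustered fire
footprints, five collapsed cover classes of differing flammability, smooth
spatial climate/topography covariate fields, and — critically — a tunable
post-fire *refractory* feedback: for ``tau`` years after a cell burns, its
ignition/spread weight is multiplied by ``rho`` (0 = full suppression of
reburning, 1 = no feedback).  This is the self-regulation mechanism whose
detection the null model is designed for.

Fires are grown as weighted clusters: ignite at a cell drawn with
probability proportional to its selection weight (cover flammability x
refractory factor), then repeatedly annex a random boundary cell with
probability proportional to its weight, until the year's target burned
fraction is met.  The mechanism is deliberately minimal — contiguous,
cover-biased, feedback-aware footprints — not a physical fire-behavior
model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .fire_history import (
    SamplePointSet,
    SeverityStack,
    sample_point_grid,
    write_severity_stack,
)

logger = logging.getLogger(__name__)

COVER_CLASSES = (
    "coniferous",
    "broadleaf",
    "shrub_herbaceous",
    "barren_sparse",
    "wetland",
)

#: Relative flammability by cover class.  Conifer stands carry the most
#: ladder/canopy fuel; broadleaf stands are moist and fire-resistant.
DEFAULT_COVER_WEIGHTS: dict[str, float] = {
    "coniferous": 1.0,
    "broadleaf": 0.3,
    "shrub_herbaceous": 0.7,
    "barren_sparse": 0.2,
    "wetland": 0.4,
}

#: Landscape composition; conifer forest dominates, as in interior Alaska.
DEFAULT_COVER_FRACTIONS: dict[str, float] = {
    "coniferous": 0.45,
    "broadleaf": 0.10,
    "shrub_herbaceous": 0.20,
    "barren_sparse": 0.10,
    "wetland": 0.15,
}

_ECOREGIONS = (
    "interior_lowlands",
    "interior_highlands",
    "yukon_flats",
    "interior_bottomlands",
)

# RNG stream salts so landscape and fire history are independently seeded
# from one master seed.
_SALT_LANDSCAPE = 104729
_SALT_FIRE = 7919
_SALT_TABLE = 15485863


@dataclass
class SimConfig:
    """Parameters of one synthetic fire-landscape realization.

    ``burn_fraction`` may be a scalar or one value per year; the default
    ramps upward so that roughly a fifth of the landscape burns at least
    once over the 33-year record, mirroring an intensifying fire regime.
    ``cover_weights`` values may likewise be scalar or per-year sequences
    (time-varying flammability).
    """

    grid_shape: tuple[int, int] = (100, 100)
    cell_size: float = 1000.0
    years: tuple[int, ...] = tuple(range(1984, 2017))
    burn_fraction: float | Sequence[float] | None = None
    n_fires_per_year: int = 16
    refractory_tau: int = 10
    refractory_rho: float = 0.1
    cover_weights: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_COVER_WEIGHTS)
    )
    cover_fractions: Mapping[str, float] | None = None
    n_cover_patches: int = 40
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.refractory_rho <= 1.0:
            raise ValueError("refractory_rho must be in [0, 1]")
        if self.refractory_tau < 0:
            raise ValueError("refractory_tau must be >= 0")
        if not self.cover_weights:
            raise ValueError("cover_weights must name at least one class")
        if self.burn_fraction is None:
            self.burn_fraction = np.linspace(0.004, 0.011, len(self.years))
        frac = np.broadcast_to(
            np.asarray(self.burn_fraction, dtype=float), (len(self.years),)
        ).copy()
        if (frac < 0).any() or (frac > 1).any():
            raise ValueError("burn_fraction values must be in [0, 1]")
        self.burn_fraction = frac

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.cover_weights)

    def weight_matrix(self) -> np.ndarray:
        """Per-year class flammability, shape (n_years, n_classes)."""
        n_years = len(self.years)
        cols = []
        for cls in self.classes:
            w = np.broadcast_to(
                np.asarray(self.cover_weights[cls], dtype=float), (n_years,)
            )
            cols.append(w)
        return np.stack(cols, axis=1)


@dataclass
class SyntheticLandscape:
    """Gridded cover, covariate fields, ecoregions and (after simulation)
    annual burn masks."""

    cover: np.ndarray  # int8 class indices into ``classes``
    classes: tuple[str, ...]
    covariates: dict[str, np.ndarray]
    ecoregion: np.ndarray  # int8 indices into ecoregion_names
    ecoregion_names: tuple[str, ...]
    config: SimConfig
    burn_masks: np.ndarray | None = None  # (n_years, rows, cols) uint8

    @property
    def extent(self) -> tuple[float, float, float, float]:
        rows, cols = self.cover.shape
        return (0.0, 0.0, cols * self.config.cell_size, rows * self.config.cell_size)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, n_waves: int = 6) -> np.ndarray:
    """Standardized sum of low-frequency random cosine surfaces."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    out = np.zeros(shape, dtype=float)
    for _ in range(n_waves):
        fx = rng.uniform(0.3, 2.5)
        fy = rng.uniform(0.3, 2.5)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.normal(1.0, 0.3)
        out += amp * np.cos(2.0 * np.pi * (fx * xx / cols + fy * yy / rows) + phi)
    sd = out.std()
    return (out - out.mean()) / (sd if sd > 0 else 1.0)


def make_landscape(config: SimConfig) -> SyntheticLandscape:
    """Build cover and covariate fields (no fires yet); deterministic in seed.

    Cover is drawn as contiguous patches: random patch seeds labelled by the
    target class fractions, cells assigned to the nearest seed (a Voronoi
    mosaic), so classes form clusters rather than iid noise.
    """
    rng = np.random.default_rng([config.seed, _SALT_LANDSCAPE])
    rows, cols = config.grid_shape
    classes = config.classes

    fractions = config.cover_fractions or {
        c: DEFAULT_COVER_FRACTIONS.get(c, 1.0) for c in classes
    }
    p = np.array([fractions.get(c, 0.0) for c in classes], dtype=float)
    if p.sum() <= 0:
        raise ValueError("cover_fractions assign zero mass to every class")
    p = p / p.sum()

    if len(classes) == 1:
        cover = np.zeros((rows, cols), dtype=np.int8)
    else:
        n_patch = max(len(classes), config.n_cover_patches)
        seeds_r = rng.uniform(0, rows, n_patch)
        seeds_c = rng.uniform(0, cols, n_patch)
        seed_cls = rng.choice(len(classes), size=n_patch, p=p)
        yy, xx = np.mgrid[0:rows, 0:cols]
        d2 = (yy.ravel()[:, None] - seeds_r) ** 2 + (xx.ravel()[:, None] - seeds_c) ** 2
        cover = seed_cls[np.argmin(d2, axis=1)].astype(np.int8).reshape(rows, cols)

    elevation = 500.0 + 250.0 * _smooth_field((rows, cols), rng)
    dzdy, dzdx = np.gradient(elevation, config.cell_size)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        aspect = (np.degrees(np.arctan2(-dzdx, dzdy)) + 360.0) % 360.0
    aspect[grad < 1e-12] = np.nan  # flat cells flagged

    covariates = {
        "slope": slope,
        "aspect": aspect,
        "elev": elevation,
        "AnnualMeanTemp": -3.0 + 2.0 * _smooth_field((rows, cols), rng),
        "TempWarmestQ": 15.0 + 2.0 * _smooth_field((rows, cols), rng),
        "TempColdestQ": -20.0 + 3.0 * _smooth_field((rows, cols), rng),
        "TempSeasonality": 12.0 + 2.0 * _smooth_field((rows, cols), rng),
        "AnnualPrecip": 300.0 + 80.0 * _smooth_field((rows, cols), rng),
        "PrecipWettestQ": 120.0 + 35.0 * _smooth_field((rows, cols), rng),
        "PrecipDriestQ": 25.0 + 10.0 * _smooth_field((rows, cols), rng),
        "PrecipWarmestQ": 90.0 + 30.0 * _smooth_field((rows, cols), rng),
        "PrecipColdestQ": 40.0 + 15.0 * _smooth_field((rows, cols), rng),
        "PrecipSeasonality": 40.0 + 10.0 * _smooth_field((rows, cols), rng),
    }

    eco = (
        (np.arange(rows)[:, None] >= rows // 2).astype(np.int8) * 2
        + (np.arange(cols)[None, :] >= cols // 2).astype(np.int8)
    )
    return SyntheticLandscape(
        cover=cover,
        classes=classes,
        covariates=covariates,
        ecoregion=eco,
        ecoregion_names=_ECOREGIONS,
        config=config,
    )


def simulate_fire_history(
    landscape: SyntheticLandscape, config: SimConfig | None = None
) -> np.ndarray:
    """Simulate annual burn masks with the refractory feedback; returns the
    (n_years, rows, cols) uint8 mask array and stores it on the landscape.

    Per year, cell selection weight = cover flammability x (``rho`` if the
    cell burned within the previous ``tau`` years else 1).  Fires grow from
    weighted random ignitions until the year's target fraction burns; if
    every remaining cell has zero weight the shortfall is logged.
    """
    cfg = config or landscape.config
    rng = np.random.default_rng([cfg.seed, _SALT_FIRE])
    rows, cols = landscape.cover.shape
    n_cells = rows * cols
    cover_flat = landscape.cover.ravel().astype(int)
    weight_matrix = cfg.weight_matrix()

    # flattened 4-neighborhoods
    idx = np.arange(n_cells)
    r, c = divmod(idx, cols)
    neighbors = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        nb = np.where(ok, rr * cols + cc, -1)
        neighbors.append(nb)
    neighbors = np.stack(neighbors, axis=1)  # (n_cells, 4), -1 = off-grid

    last_burn = np.full(n_cells, -(10**9), dtype=np.int64)
    masks = np.zeros((len(cfg.years), rows, cols), dtype=np.uint8)

    for t, year in enumerate(cfg.years):
        target = int(round(cfg.burn_fraction[t] * n_cells))
        if target == 0:
            continue
        base_w = weight_matrix[t][cover_flat]
        refractory = (year - last_burn) <= cfg.refractory_tau
        w = np.where(refractory, base_w * cfg.refractory_rho, base_w)
        burned_now = np.zeros(n_cells, dtype=bool)
        n_burned = 0

        # split the year's target area across fires (remainder to the first)
        n_fires = max(1, cfg.n_fires_per_year)
        per_fire = [target // n_fires] * n_fires
        for i in range(target % n_fires):
            per_fire[i] += 1

        for fire_target in per_fire:
            if fire_target == 0 or n_burned >= target:
                break
            ignitable = w * ~burned_now
            total = ignitable.sum()
            if total <= 0:
                logger.warning(
                    "year %d: no ignitable cells remain; burned %d of %d target",
                    year, n_burned, target,
                )
                break
            start = rng.choice(n_cells, p=ignitable / total)
            burned_now[start] = True
            n_burned += 1
            fire_size = 1
            frontier: dict[int, float] = {}
            for nb in neighbors[start]:
                if nb >= 0 and not burned_now[nb] and w[nb] > 0:
                    frontier[int(nb)] = w[nb]
            while fire_size < fire_target and n_burned < target and frontier:
                cells = list(frontier)
                wts = np.fromiter(frontier.values(), dtype=float, count=len(cells))
                pick = cells[_weighted_index(rng, wts)]
                del frontier[pick]
                if burned_now[pick]:
                    continue
                burned_now[pick] = True
                n_burned += 1
                fire_size += 1
                for nb in neighbors[pick]:
                    if nb >= 0 and not burned_now[nb] and w[nb] > 0:
                        frontier[int(nb)] = w[nb]
            if not frontier and fire_size < fire_target:
                logger.debug(
                    "year %d: fire stalled at %d of %d cells", year, fire_size, fire_target
                )

        if n_burned < target:
            logger.warning(
                "year %d: burned %d cells of target %d (refractory/flammability limits)",
                year, n_burned, target,
            )
        last_burn[burned_now] = year
        masks[t] = burned_now.reshape(rows, cols).astype(np.uint8)

    landscape.burn_masks = masks
    return masks


def _weighted_index(rng: np.random.Generator, weights: np.ndarray) -> int:
    """Draw an index with probability proportional to weights (small arrays)."""
    cum = np.cumsum(weights)
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right"))


def to_severity_stack(landscape: SyntheticLandscape) -> SeverityStack:
    """Encode burn masks as a severity stack: burned cells class 3,
    unburned class 1 (so the >=2 reclassification threshold is exercised)."""
    if landscape.burn_masks is None:
        raise ValueError("simulate_fire_history has not been run")
    grids = np.where(landscape.burn_masks > 0, 3, 1).astype(np.int16)
    rows, _ = landscape.cover.shape
    return SeverityStack(
        years=tuple(landscape.config.years),
        grids=grids,
        cell_size=landscape.config.cell_size,
        x_min=0.0,
        y_max=rows * landscape.config.cell_size,
        nodata=-9999,
    )


def landscape_points(
    landscape: SyntheticLandscape, spacing: float | None = None
) -> SamplePointSet:
    """Uniform sample lattice over the landscape with covariates attached
    (values read from the underlying fields at each point's cell)."""
    spacing = spacing if spacing is not None else 2.0 * landscape.config.cell_size
    points = sample_point_grid(landscape.extent, spacing)
    rows, cols = landscape.cover.shape
    cell = landscape.config.cell_size
    col = np.clip((points.x / cell).astype(int), 0, cols - 1)
    row = np.clip(((rows * cell - points.y) / cell).astype(int), 0, rows - 1)
    data = {name: fld[row, col] for name, fld in landscape.covariates.items()}
    data["ecoregion"] = np.asarray(landscape.ecoregion_names)[
        landscape.ecoregion[row, col]
    ]
    data["cover"] = np.asarray(landscape.classes)[landscape.cover[row, col]]
    points.covariates = pd.DataFrame(data, index=pd.Index(points.ids, name="id"))
    return points


def write_history(
    landscape: SyntheticLandscape,
    outdir: str | Path,
    spacing: float | None = None,
) -> dict[str, object]:
    """Write the simulated record in the ingest contract's formats:
    ``severity_<YYYY>.tif`` GeoTIFFs plus a point-covariate CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = to_severity_stack(landscape)
    raster_paths = write_severity_stack(stack, outdir)
    points = landscape_points(landscape, spacing)
    cov = points.covariates.copy()
    cov.insert(0, "y", points.y)
    cov.insert(0, "x", points.x)
    cov_path = outdir / "covariates.csv"
    cov.to_csv(cov_path, index=True, index_label="id")
    return {"rasters": raster_paths, "covariates": cov_path, "n_points": len(points)}


# ---------------------------------------------------------------------------
# Tabular generator for the predictability (classification) analysis


PRECIP_VARS = ("PrecipWettestQ", "PrecipDriestQ", "PrecipColdestQ", "PrecipSeasonality")
TEMP_VARS = ("TempWarmestQ", "TempColdestQ", "AnnualMeanTemp", "TempSeasonality")
TOPO_VARS = ("slope", "aspect", "elev")

_PRECIP_SCALE = {
    "PrecipWettestQ": (120.0, 35.0),
    "PrecipDriestQ": (25.0, 10.0),
    "PrecipColdestQ": (40.0, 15.0),
    "PrecipSeasonality": (40.0, 10.0),
}
_TEMP_SCALE = {
    "TempWarmestQ": (15.0, 2.0),
    "TempColdestQ": (-20.0, 3.0),
    "AnnualMeanTemp": (-3.0, 2.0),
    "TempSeasonality": (12.0, 2.0),
}


def bayes_accuracy(beta: float) -> float:
    """Accuracy of the Bayes classifier when the reburn log-odds are
    ``beta * z`` with z ~ N(0,1): E[sigmoid(beta * |Z|)]."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    val, _ = integrate.quad(
        lambda z: special.expit(beta * abs(z))
        * math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi),
        -np.inf, np.inf,
    )
    return val


def beta_for_bayes_accuracy(accuracy: float = 0.8) -> float:
    """Signal strength giving the requested Bayes accuracy (in (0.5, 1))."""
    if not 0.5 < accuracy < 1.0:
        raise ValueError("accuracy must be in (0.5, 1)")
    return optimize.brentq(lambda b: bayes_accuracy(b) - accuracy, 1e-9, 60.0)


def make_classification_table(
    n: int = 2816,
    seed: int = 0,
    bayes_acc: float = 0.8,
    within_group_corr: float = 0.2,
) -> pd.DataFrame:
    """Point-level feature table for single-fire vs reburn classification.

    Only the precipitation variables carry signal: the reburn log-odds are
    ``beta * z`` where z is the standardized mean of the four (correlated)
    precipitation variables and beta is set so the Bayes accuracy equals
    ``bayes_acc``.  Temperature variables are correlated among themselves
    but independent of the label; topography is independent noise.  The
    label column ``fires`` is 1 (single fire) or 2 (reburn); aspect is
    already on the folded 0-1 scale.

    ``within_group_corr`` balances two requirements: large enough that the
    correlation screen always places the group members in each other's
    conditioning sets, small enough that each variable's idiosyncratic
    component keeps a material share of the signal (with equicorrelation r
    in a group of 4, the unique share is (1-r)/4 / (r + (1-r)/4)), so every
    precipitation variable is individually informative.
    """
    rng = np.random.default_rng([seed, _SALT_TABLE])
    r = within_group_corr

    def _group(names):
        f = rng.standard_normal(n)
        z = {}
        for name in names:
            z[name] = math.sqrt(r) * f + math.sqrt(1 - r) * rng.standard_normal(n)
        return z

    precip_z = _group(PRECIP_VARS)
    temp_z = _group(TEMP_VARS)

    mean_z = np.mean([precip_z[v] for v in PRECIP_VARS], axis=0)
    k = len(PRECIP_VARS)
    mean_sd = math.sqrt(r + (1 - r) / k)
    z = mean_z / mean_sd  # exactly N(0,1)

    beta = beta_for_bayes_accuracy(bayes_acc)
    p_reburn = special.expit(beta * z)
    label = (rng.random(n) < p_reburn).astype(int) + 1  # 1 single, 2 reburn

    data = {}
    for name in PRECIP_VARS:
        mu, sd = _PRECIP_SCALE[name]
        data[name] = mu + sd * precip_z[name]
    for name in TEMP_VARS:
        mu, sd = _TEMP_SCALE[name]
        data[name] = mu + sd * temp_z[name]
    data["slope"] = np.abs(rng.normal(5.0, 4.0, n))
    data["aspect"] = rng.random(n)  # folded aspect scale
    data["elev"] = rng.normal(500.0, 200.0, n)
    data["fires"] = label
    df = pd.DataFrame(data)
    df.attrs["beta"] = beta
    df.attrs["bayes_accuracy"] = bayes_acc
    return df
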