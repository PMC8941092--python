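"""Burn-history extraction from annual burn-severity rasters.

Annual severity products (MTBS-style) encode each 30 m cell as an integer
severity class.  This module reduces a stack of such rasters to per-point
burn-year sequences on a uniform sampling lattice: reclassify severity to
burned/unburned, lay a regular point grid over the raster extent, and read
each point's burn years off the stack.

Rasters are single-band integer GeoTIFFs, one file per calendar year, named
``severity_<YYYY>.tif``.  Georeferencing uses the standard GeoTIFF
ModelPixelScale/ModelTiepoint tags; coordinates are planar map units
(a projected CRS is assumed throughout — no geodesic computation).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Severity classes below this value count as unburned by default.
DEFAULT_BURN_THRESHOLD = 2

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class SeverityStack:
    """A stack of co-registered annual integer severity rasters.

    ``grids`` has shape ``(n_years, rows, cols)``; row 0 is the northern
    edge.  ``x_min``/``y_max`` locate the outer corner of the upper-left
    cell; ``cell_size`` is the square cell pitch in map units.
    """

    years: tuple[int, ...]
    grids: np.ndarray
    cell_size: float
    x_min: float = 0.0
    y_max: float | None = None
    nodata: int = -9999

    def __post_init__(self):
        grids = np.asarray(self.grids)
        if grids.ndim != 3 or grids.shape[0] != len(self.years):
            raise ValueError("grids must be (n_years, rows, cols) matching years")
        if not np.issubdtype(grids.dtype, np.integer):
            raise TypeError("severity grids must be integer-valued")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "grids", grids)
        if self.y_max is None:
            object.__setattr__(self, "y_max", grids.shape[1] * float(self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster footprint."""
        rows, cols = self.shape
        return (
            self.x_min,
            self.y_max - rows * self.cell_size,
            self.x_min + cols * self.cell_size,
            self.y_max,
        )


@dataclass
class SamplePointSet:
    """A uniform lattice of sample points, optionally with covariates.

    ``covariates`` is a DataFrame indexed by point id; it is attached by
    :func:`attach_covariates`.
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spacing: float
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("point ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class BurnHistory:
    """Ordered burn years observed at one sample point."""

    point_id: int
    burn_years: tuple[int, ...]

    def __post_init__(self):
        if list(self.burn_years) != sorted(set(self.burn_years)):
            raise ValueError("burn_years must be strictly increasing")

    @property
    def n_burns(self) -> int:
        return len(self.burn_years)


def classify_burned(
    grid: np.ndarray,
    threshold: int = DEFAULT_BURN_THRESHOLD,
    nodata: int | None = None,
    unburned_classes: Sequence[int] = (),
) -> np.ndarray:
    """Reclassify an integer severity grid to a binary burned mask.

    Cells with severity >= ``threshold`` are burned (1), everything else —
    including nodata — is unburned (0).  ``unburned_classes`` optionally
    forces additional classes (e.g. MTBS 5 "increased greenness" and 6
    "non-mapping") to unburned; the default follows the literal
    below-threshold rule.
    """
    grid = np.asarray(grid)
    if not np.issubdtype(grid.dtype, np.integer):
        raise TypeError(f"severity grid must be integer-valued, got {grid.dtype}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    valid = np.ones(grid.shape, dtype=bool)
    if nodata is not None:
        valid = grid != nodata
        if not valid.any():
            warnings.warn("severity grid is all nodata; returning all-zero mask")
    mask = (grid >= threshold) & valid
    for cls in unburned_classes:
        mask &= grid != cls
    return mask.astype(np.uint8)


def sample_point_grid(
    extent: tuple[float, float, float, float], spacing: float
) -> SamplePointSet:
    """Lay a regular square lattice of pitch ``spacing`` inside ``extent``.

    Points sit at the centers of full lattice cells anchored at the extent's
    lower-left corner; only cells fitting entirely inside the (closed) extent
    produce a point.  A spacing exceeding the extent yields an empty set with
    a warning.
    """
    x_min, y_min, x_max, y_max = extent
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if x_max <= x_min or y_max <= y_min:
        raise ValueError("extent is degenerate")
    eps = 1e-9 * spacing
    nx = int(np.floor((x_max - x_min) / spacing + eps))
    ny = int(np.floor((y_max - y_min) / spacing + eps))
    if nx == 0 or ny == 0:
        warnings.warn(
            f"spacing {spacing} exceeds extent {extent}; empty sample set"
        )
        return SamplePointSet(
            ids=np.array([], dtype=int),
            x=np.array([]),
            y=np.array([]),
            spacing=spacing,
        )
    xs = x_min + spacing * (np.arange(nx) + 0.5)
    ys = y_min + spacing * (np.arange(ny) + 0.5)
    xx, yy = np.meshgrid(xs, ys)
    return SamplePointSet(
        ids=np.arange(xx.size, dtype=int),
        x=xx.ravel(),
        y=yy.ravel(),
        spacing=spacing,
    )


def _point_cells(
    stack: SeverityStack, points: SamplePointSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map point coordinates to (row, col); returns (inside, row, col)."""
    x_min, y_min, x_max, y_max = stack.extent
    rows, cols = stack.shape
    inside = (
        (points.x >= x_min)
        & (points.x <= x_max)
        & (points.y >= y_min)
        & (points.y <= y_max)
    )
    col = np.floor((points.x - x_min) / stack.cell_size).astype(int)
    row = np.floor((stack.y_max - points.y) / stack.cell_size).astype(int)
    # closed extent: points on the far/top edge land in the last cell
    col = np.clip(col, 0, cols - 1)
    row = np.clip(row, 0, rows - 1)
    return inside, row, col


def extract_burn_histories(
    stack: SeverityStack,
    points: SamplePointSet,
    threshold: int = DEFAULT_BURN_THRESHOLD,
    unburned_classes: Sequence[int] = (),
) -> list[BurnHistory]:
    """Extract the ascending burn-year sequence at every sample point.

    Points outside the raster extent are excluded with their ids logged.
    """
    inside, row, col = _point_cells(stack, points)
    if not inside.all():
        excluded = points.ids[~inside]
        logger.warning(
            "%d points outside raster extent excluded: %s",
            len(excluded),
            excluded.tolist()[:20],
        )
    burned = np.stack(
        [
            classify_burned(g, threshold, stack.nodata, unburned_classes)
            for g in stack.grids
        ]
    )  # (n_years, rows, cols)
    years = np.asarray(stack.years)
    histories: list[BurnHistory] = []
    hit = burned[:, row[inside], col[inside]]  # (n_years, n_inside)
    for j, pid in enumerate(points.ids[inside]):
        yrs = tuple(int(y) for y in years[hit[:, j] > 0])
        histories.append(BurnHistory(point_id=int(pid), burn_years=yrs))
    return histories


def attach_covariates(
    points: SamplePointSet, table: pd.DataFrame, id_col: str = "id"
) -> SamplePointSet:
    """Join a covariate table onto the point set by point id.

    Points without a complete covariate record are dropped (counted in the
    log).  Duplicate ids in the table and empty joins are hard errors.
    """
    if id_col in table.columns:
        table = table.set_index(id_col)
    dup = table.index[table.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate point id(s) in covariate table: {dup.tolist()}")
    table = table.drop(columns=[c for c in ("x", "y") if c in table.columns])
    matched = table.reindex(points.ids)
    complete = ~matched.isna().any(axis=1)
    n_keep = int(complete.sum())
    if n_keep == 0:
        raise ValueError("no points could be joined to the covariate table")
    n_drop = len(points) - n_keep
    if n_drop:
        logger.warning("dropped %d points with missing covariates", n_drop)
    keep = complete.to_numpy()
    return SamplePointSet(
        ids=points.ids[keep],
        x=points.x[keep],
        y=points.y[keep],
        spacing=points.spacing,
        covariates=matched.loc[complete],
    )


# ---------------------------------------------------------------------------
# GeoTIFF + CSV round trips


def write_severity_raster(
    path: str | Path,
    grid: np.ndarray,
    cell_size: float,
    x_min: float,
    y_max: float,
    nodata: int = -9999,
) -> None:
    """Write one integer severity grid as a georeferenced GeoTIFF."""
    tifffile.imwrite(
        str(path),
        np.asarray(grid, dtype=np.int16),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x_min), float(y_max), 0.0)),
            (_TAG_GDAL_NODATA, "s", None, str(nodata)),
        ],
    )


def write_severity_stack(stack: SeverityStack, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for year, grid in zip(stack.years, stack.grids):
        p = outdir / f"severity_{year}.tif"
        write_severity_raster(
            p, grid, stack.cell_size, stack.x_min, stack.y_max, stack.nodata
        )
        paths.append(p)
    return paths


def read_severity_stack(
    directory: str | Path, pattern: str = "severity_*.tif"
) -> SeverityStack:
    """Read ``severity_<YYYY>.tif`` files from a directory into a stack."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no rasters matching {pattern!r} in {directory}")
    years, grids = [], []
    cell_size = x_min = y_max = nodata = None
    for f in files:
        m = re.search(r"(\d{4})", f.stem)
        if not m:
            raise ValueError(f"cannot parse year from filename {f.name}")
        years.append(int(m.group(1)))
        with tifffile.TiffFile(str(f)) as tf:
            page = tf.pages[0]
            grids.append(page.asarray())
            tags = page.tags
            if _TAG_PIXEL_SCALE in tags:
                cell_size = float(tags[_TAG_PIXEL_SCALE].value[0])
            if _TAG_TIEPOINT in tags:
                tp = tags[_TAG_TIEPOINT].value
                x_min, y_max = float(tp[3]), float(tp[4])
            if _TAG_GDAL_NODATA in tags:
                nodata = int(float(tags[_TAG_GDAL_NODATA].value))
    order = np.argsort(years)
    return SeverityStack(
        years=tuple(np.asarray(years)[order]),
        grids=np.stack([grids[i] for i in order]),
        cell_size=cell_size if cell_size is not None else 1.0,
        x_min=x_min if x_min is not None else 0.0,
        y_max=y_max,
        nodata=nodata if nodata is not None else -9999,
    )


def histories_to_frame(
    histories: Sequence[BurnHistory], points: SamplePointSet | None = None
) -> pd.DataFrame:
    """Tabulate burn histories as ``id, x, y, n_burns, burn_years`` rows."""
    coords: Mapping[int, tuple[float, float]] = {}
    if points is not None:
        coords = {int(i): (x, y) for i, x, y in zip(points.ids, points.x, points.y)}
    rows = []
    for h in histories:
        x, y = coords.get(h.point_id, (np.nan, np.nan))
        rows.append(
            {
                "id": h.point_id,
                "x": x,
                "y": y,
                "n_burns": h.n_burns,
                "burn_years": "|".join(str(b) for b in h.burn_years),
            }
        )
    return pd.DataFrame(rows, columns=["id", "x", "y", "n_burns", "burn_years"])


def write_histories(
    histories: Sequence[BurnHistory],
    path: str | Path,
    points: SamplePointSet | None = None,
) -> None:
    histories_to_frame(histories, points).to_csv(path, index=False)


def read_histories(path: str | Path) -> list[BurnHistory]:
    df = pd.read_csv(path, dtype={"burn_years": str}, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        yrs = tuple(int(s) for s in str(r["burn_years"]).split("|") if s)
        out.append(BurnHistory(point_id=int(r["id"]), burn_years=yrs))
    return out
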