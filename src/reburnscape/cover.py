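"""Cover-type composition of reburns and the conifer reburn-share trend.

Satellite landcover legends are collapsed to five classes — coniferous,
broadleaf, shrub/herbaceous, barren/sparse, wetland (incl. bogs and fens) —
and each reburn event (a successive burn pair whose interval fits the
window) is attributed to its point's beginning-of-record cover class: no
successional update is attempted between fires, on the assumption that
conifers regenerate after a single fire irrespective of severity.  The
conifer share of reburns per focal year is then regressed on year with
weights equal to the number of qualifying reburn points in that year.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fire_history import BurnHistory
from .trends import TrendEstimate, weighted_linreg

logger = logging.getLogger(__name__)

COVER_CLASSES = (
    "coniferous",
    "broadleaf",
    "shrub_herbaceous",
    "barren_sparse",
    "wetland",
)

#: Editable collapse of a satellite dominant-landcover legend onto the five
#: analysis classes (ABoVE-style labels; extend via a two-column CSV).
DEFAULT_LANDCOVER_MAPPING: dict[str, str] = {
    "Evergreen Forest": "coniferous",
    "Woodland": "coniferous",
    "Mixed Forest": "coniferous",
    "Deciduous Forest": "broadleaf",
    "Low Shrub": "shrub_herbaceous",
    "Tall Shrub": "shrub_herbaceous",
    "Open Shrubs": "shrub_herbaceous",
    "Herbaceous": "shrub_herbaceous",
    "Tussock Tundra": "shrub_herbaceous",
    "Sparsely Vegetated": "barren_sparse",
    "Barren": "barren_sparse",
    "Fen": "wetland",
    "Bog": "wetland",
    "Shallows/Littoral": "wetland",
    # identity entries so pre-collapsed tables pass through unchanged
    "coniferous": "coniferous",
    "broadleaf": "broadleaf",
    "shrub_herbaceous": "shrub_herbaceous",
    "barren_sparse": "barren_sparse",
    "wetland": "wetland",
}


def load_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column ``source_label,cover_class`` CSV."""
    df = pd.read_csv(path)
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    bad = sorted(set(mapping.values()) - set(COVER_CLASSES))
    if bad:
        raise ValueError(f"mapping targets outside the five classes: {bad}")
    return mapping


def collapse_landcover(
    raw_class: str, mapping: Mapping[str, str] | None = None
) -> str:
    """Deterministic legend lookup; unmapped labels are an error."""
    mapping = DEFAULT_LANDCOVER_MAPPING if mapping is None else mapping
    try:
        out = mapping[raw_class]
    except KeyError:
        raise KeyError(
            f"landcover label {raw_class!r} has no entry in the collapse mapping"
        ) from None
    if out not in COVER_CLASSES:
        raise ValueError(f"mapping sends {raw_class!r} to unknown class {out!r}")
    return out


def cover_reburn_proportions(
    histories: Sequence[BurnHistory],
    cover: Mapping[int, str],
    window_length: int,
    record_years: Sequence[int],
) -> pd.DataFrame:
    """Per-focal-year cover composition of qualifying reburns.

    A point contributes to focal year t when it has successive burns
    (y1, y2) with y2 = t and t - y1 <= window_length; points with 3+ burns
    contribute each successive pair independently.  Focal years begin at
    record start + window_length (earlier years cannot observe a full
    interval).  Years with zero qualifying reburns keep their row with NaN
    proportions and are excluded from trend fitting.
    """
    record = sorted(record_years)
    focal_years = [y for y in record if y >= record[0] + window_length]
    counts = {y: {c: 0 for c in COVER_CLASSES} for y in focal_years}
    missing: set[int] = set()
    for h in histories:
        for y1, y2 in zip(h.burn_years, h.burn_years[1:]):
            if y2 in counts and (y2 - y1) <= window_length:
                cls = cover.get(h.point_id)
                if cls is None:
                    missing.add(h.point_id)
                    continue
                if cls not in COVER_CLASSES:
                    raise ValueError(
                        f"point {h.point_id} has unknown cover class {cls!r}"
                    )
                counts[y2][cls] += 1
    if missing:
        logger.warning("%d reburn points lack a cover class; skipped", len(missing))
    rows = []
    for y in focal_years:
        n = sum(counts[y].values())
        row = {"focal_year": y, "window": window_length, "n_reburns": n}
        for c in COVER_CLASSES:
            row[c] = counts[y][c] / n if n > 0 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["n_reburns"].sum() == 0:
        logger.warning("no qualifying reburns anywhere in the record")
    return df


def conifer_trend(tables: pd.DataFrame) -> TrendEstimate:
    """Weighted least-squares trend of the conifer share of reburns vs.
    focal year, weights = number of reburn points per year."""
    valid = tables[tables["n_reburns"] > 0]
    if len(valid) < 3:
        raise ValueError(
            f"need >= 3 focal years with reburns, have {len(valid)}"
        )
    return weighted_linreg(
        valid["focal_year"].to_numpy(),
        valid["coniferous"].to_numpy(),
        valid["n_reburns"].to_numpy(),
    )
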