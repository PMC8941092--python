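"""Burn/reburn accounting and fire-interval distributions.

Per-point burn histories are reduced to (a) stratified burned/reburned
percentage tables — what fraction of the landscape burned at all, and of
those points how many burned once, twice, or three-plus times — and
(b) between-fire interval records with their empirical cumulative
distribution and upper-tail fractions.  Reburn percentages use burned
points as the denominator; the ECDF is truncated at a configurable maximum
interval because long intervals have progressively less opportunity to be
observed inside a finite record (right-censoring; no formal correction is
applied, the truncation is reported instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fire_history import BurnHistory

logger = logging.getLogger(__name__)

DEFAULT_MAX_INTERVAL = 16


@dataclass(frozen=True)
class BurnCountSummary:
    """Burned / single / double / triple-plus percentages for one stratum.

    ``pct_burned_overall`` is relative to all points in the stratum; the
    single/two/three-plus percentages are relative to burned points only
    and sum to 100 (up to rounding).
    """

    stratum: str
    n_points: int
    n_burned: int
    pct_burned_overall: float
    pct_single: float
    pct_two: float
    pct_three_plus: float
    no_burned_flag: bool = False


@dataclass(frozen=True)
class EcdfResult:
    """ECDF of fire intervals, truncated at ``max_interval`` years."""

    table: pd.DataFrame  # columns: interval, cum_fraction
    max_interval: int
    n_used: int
    n_truncated: int


def burn_count_summary(
    histories: Sequence[BurnHistory],
    strata: Mapping[int, str] | None = None,
) -> list[BurnCountSummary]:
    """Summarize burn counts overall and (optionally) per stratum.

    A stratum with zero burned points is reported with zero percentages and
    flagged rather than erroring.
    """
    if not histories:
        raise ValueError("histories must be non-empty")
    counts = pd.Series({h.point_id: h.n_burns for h in histories})
    labels = pd.Series(
        {pid: (strata.get(pid, "unassigned") if strata else "overall")
         for pid in counts.index}
    )
    out: list[BurnCountSummary] = []
    groups = [("overall", counts)]
    if strata is not None:
        groups += [(lab, counts[labels == lab]) for lab in sorted(labels.unique())]
    for lab, sub in groups:
        n = len(sub)
        burned = sub[sub >= 1]
        nb = len(burned)
        if nb == 0:
            out.append(
                BurnCountSummary(lab, n, 0, 0.0, 0.0, 0.0, 0.0, no_burned_flag=True)
            )
            continue
        out.append(
            BurnCountSummary(
                stratum=lab,
                n_points=n,
                n_burned=nb,
                pct_burned_overall=100.0 * nb / n,
                pct_single=100.0 * (burned == 1).sum() / nb,
                pct_two=100.0 * (burned == 2).sum() / nb,
                pct_three_plus=100.0 * (burned >= 3).sum() / nb,
            )
        )
    return out


def summary_frame(summaries: Sequence[BurnCountSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def fire_intervals(histories: Sequence[BurnHistory]) -> pd.DataFrame:
    """One record per successive burn pair: columns point_id, interval,
    first_year.  A 3-burn point contributes 2 intervals (successive pairs
    only, not all pairwise combinations)."""
    rows = []
    for h in histories:
        for y1, y2 in zip(h.burn_years, h.burn_years[1:]):
            rows.append({"point_id": h.point_id, "interval": y2 - y1, "first_year": y1})
    return pd.DataFrame(rows, columns=["point_id", "interval", "first_year"])


def interval_ecdf(
    intervals: pd.DataFrame | Sequence[int],
    max_interval: int = DEFAULT_MAX_INTERVAL,
) -> EcdfResult:
    """ECDF of intervals on [1, max_interval].

    Fractions are relative to intervals <= ``max_interval`` only; the count
    truncated away is reported in the result metadata.
    """
    if max_interval < 1:
        raise ValueError("max_interval must be >= 1")
    vals = _interval_values(intervals)
    if vals.size == 0:
        raise ValueError("no intervals to build an ECDF from")
    within = vals[vals <= max_interval]
    n_trunc = int(vals.size - within.size)
    if within.size == 0:
        raise ValueError("all intervals exceed max_interval")
    grid = np.arange(1, max_interval + 1)
    cum = np.searchsorted(np.sort(within), grid, side="right") / within.size
    table = pd.DataFrame({"interval": grid, "cum_fraction": cum})
    return EcdfResult(
        table=table,
        max_interval=max_interval,
        n_used=int(within.size),
        n_truncated=n_trunc,
    )


def interval_tail_fractions(
    intervals: pd.DataFrame | Sequence[int],
    thresholds: Sequence[int],
) -> dict[int, float]:
    """Fraction of all intervals >= each threshold (no truncation)."""
    vals = _interval_values(intervals)
    if vals.size == 0:
        raise ValueError("no intervals")
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    return {int(t): float((vals >= t).mean()) for t in thresholds}


def _interval_values(intervals: pd.DataFrame | Sequence[int]) -> np.ndarray:
    if isinstance(intervals, pd.DataFrame):
        vals = intervals["interval"].to_numpy()
    else:
        vals = np.asarray(list(intervals))
    if vals.size and (vals < 1).any():
        raise ValueError("intervals must be >= 1 year")
    return vals
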