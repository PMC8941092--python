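"""Moving-window reburn proportions and their randomized-placement null.

The self-regulation test: for each focal year, the *observed* reburn
proportion is the fraction of points burning in the focal year that also
burned in any year of the preceding W-year window.  The *null* re-places
the window-burned count n1 and the focal-year count n2 uniformly at random
over the N sample points (without replacement, no spatial interaction) and
records the overlap, repeated (default) 10,000 times.  Observed proportions
sitting below the null band indicate a negative (refractory) feedback of
recently burned areas on reburning.

Under uniform re-placement the overlap count is exactly
Hypergeometric(N, n1, n2) with mean n1*n2/N, so the expected null
proportion (overlap/n2) is n1/N; the closed form serves as an analytic
check on the Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fire_history import BurnHistory

logger = logging.getLogger(__name__)

DEFAULT_REPS = 10_000

#: How the reburn proportion is normalized: by focal-year burned points
#: (makes observed and null directly comparable per year), by the union of
#: window+focal burned points, or by all points burned anywhere in the record.
DENOMINATORS = ("focal", "union", "all_burned")


@dataclass(frozen=True)
class WindowSpec:
    """A W-year lookback window ending just before the focal year."""

    window_length: int
    focal_year: int
    lag: int = 0  # window ends ``lag`` years before the focal year

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @property
    def window_years(self) -> range:
        end = self.focal_year - self.lag
        return range(end - self.window_length, end)


@dataclass(frozen=True)
class ObservedReburn:
    focal_year: int
    proportion: float  # NaN when undefined (no focal burns)
    n_window_burned: int
    n_focal_burned: int
    n_points: int
    defined: bool


@dataclass(frozen=True)
class NullModelResult:
    """Monte-Carlo summary of the expected reburn proportion under random
    placement, conditioned on the observed margins (n1, n2)."""

    focal_year: int | None
    n_points: int
    n_window_burned: int
    n_focal_burned: int
    reps: int
    mean: float
    q25: float
    q75: float
    q05: float
    q95: float
    defined: bool = True
    draws: np.ndarray | None = None


def burned_sets(histories: Sequence[BurnHistory]) -> dict[int, set[int]]:
    """Map each calendar year to the set of point ids burning that year."""
    by_year: dict[int, set[int]] = {}
    for h in histories:
        for y in h.burn_years:
            by_year.setdefault(y, set()).add(h.point_id)
    return by_year


def observed_window_reburn(
    histories: Sequence[BurnHistory],
    spec: WindowSpec,
    record_years: Sequence[int],
    denominator: str = "focal",
) -> ObservedReburn:
    """Observed reburn proportion for one focal year.

    Errors if the window extends before the record start (such years carry
    a downward bias from unobservable earlier fires and are excluded).
    """
    record = sorted(record_years)
    if min(spec.window_years) < record[0]:
        raise ValueError(
            f"window {list(spec.window_years)[0]}-{list(spec.window_years)[-1]} "
            f"extends before record start {record[0]}"
        )
    if spec.focal_year > record[-1]:
        raise ValueError("focal year beyond record end")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    by_year = burned_sets(histories)
    window_set: set[int] = set()
    for y in spec.window_years:
        window_set |= by_year.get(y, set())
    focal_set = by_year.get(spec.focal_year, set())
    n1, n2 = len(window_set), len(focal_set)
    overlap = len(window_set & focal_set)
    if denominator == "focal":
        denom = n2
    elif denominator == "union":
        denom = len(window_set | focal_set)
    else:
        all_burned = set().union(*by_year.values()) if by_year else set()
        denom = len(all_burned)
    defined = denom > 0
    return ObservedReburn(
        focal_year=spec.focal_year,
        proportion=overlap / denom if defined else float("nan"),
        n_window_burned=n1,
        n_focal_burned=n2,
        n_points=len(histories),
        defined=defined,
    )


def expected_overlap_closed_form(
    N: int, n1: int, n2: int
) -> tuple[float, float]:
    """Expected overlap count n1*n2/N and expected proportion n1/N under
    uniform random placement (linearity of expectation over cells)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("require 0 <= n1, n2 <= N")
    count = n1 * n2 / N
    proportion = n1 / N if n2 > 0 else float("nan") if n1 else 0.0
    if n1 == 0:
        proportion = 0.0
    return count, proportion


def null_reburn_distribution(
    N: int,
    n1: int,
    n2: int,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = 0,
    focal_year: int | None = None,
    method: str = "hypergeometric",
    keep_draws: bool = False,
) -> NullModelResult:
    """Monte-Carlo null distribution of the reburn proportion.

    Each rep places n1 and n2 burned points uniformly at random (without
    replacement) over N slots and records overlap/n2.  The default sampler
    draws the overlap directly from its exact distribution,
    Hypergeometric(N, n1, n2); ``method="subsets"`` performs the literal
    two-subset draw (identical in distribution, kept for verification).
    Quartiles use the nearest-rank convention.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("require 0 <= n1, n2 <= N")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n2 == 0:
        return NullModelResult(
            focal_year, N, n1, n2, reps,
            mean=float("nan"), q25=float("nan"), q75=float("nan"),
            q05=float("nan"), q95=float("nan"), defined=False,
        )
    if method == "hypergeometric":
        overlap = rng.hypergeometric(n1, N - n1, n2, size=reps)
    elif method == "subsets":
        overlap = np.empty(reps, dtype=np.int64)
        slots = np.arange(N)
        for i in range(reps):
            a = rng.choice(slots, size=n1, replace=False)
            b = rng.choice(slots, size=n2, replace=False)
            overlap[i] = np.intersect1d(a, b, assume_unique=True).size
    else:
        raise ValueError("method must be 'hypergeometric' or 'subsets'")
    props = overlap / n2
    q05, q25, q75, q95 = np.quantile(
        props, [0.05, 0.25, 0.75, 0.95], method="inverted_cdf"
    )
    return NullModelResult(
        focal_year=focal_year,
        n_points=N,
        n_window_burned=n1,
        n_focal_burned=n2,
        reps=reps,
        mean=float(props.mean()),
        q25=float(q25),
        q75=float(q75),
        q05=float(q05),
        q95=float(q95),
        draws=props if keep_draws else None,
    )


def window_series(
    histories: Sequence[BurnHistory],
    window_length: int,
    record_years: Sequence[int],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    denominator: str = "focal",
    lag: int = 0,
) -> pd.DataFrame:
    """Observed and null reburn proportions for every admissible focal year.

    Admissible focal years are those whose full lookback window fits inside
    the record (record start + lag + W onward).  Each year's null is
    conditioned on that year's observed margins (n1, n2).
    """
    record = sorted(record_years)
    start = record[0] + window_length + lag
    focal_years = [y for y in record if y >= start]
    if not focal_years:
        raise ValueError("record too short for this window length")
    N = len(histories)
    rng = np.random.default_rng(seed)
    rows = []
    for fy in focal_years:
        spec = WindowSpec(window_length=window_length, focal_year=fy, lag=lag)
        obs = observed_window_reburn(histories, spec, record, denominator)
        null = null_reburn_distribution(
            N, obs.n_window_burned, obs.n_focal_burned, reps, rng, focal_year=fy
        )
        rows.append(
            {
                "focal_year": fy,
                "W": window_length,
                "lag": lag,
                "observed": obs.proportion,
                "null_mean": null.mean,
                "null_q25": null.q25,
                "null_q75": null.q75,
                "null_q05": null.q05,
                "null_q95": null.q95,
                "n1": obs.n_window_burned,
                "n2": obs.n_focal_burned,
                "N": N,
                "defined": obs.defined,
            }
        )
    return pd.DataFrame(rows)


def interval_band_series(
    histories: Sequence[BurnHistory],
    lo: int,
    hi: int,
    record_years: Sequence[int],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    denominator: str = "focal",
) -> pd.DataFrame:
    """Series isolating reburn intervals in (lo, hi]: the lookback window
    covers [focal - hi, focal - lo - 1].  ``lo=0`` reduces to
    :func:`window_series` with W = hi."""
    if not 0 <= lo < hi:
        raise ValueError("require 0 <= lo < hi")
    record = sorted(record_years)
    if record[0] + hi > record[-1]:
        raise ValueError("interval band extends beyond the record")
    return window_series(
        histories,
        window_length=hi - lo,
        record_years=record,
        reps=reps,
        seed=seed,
        denominator=denominator,
        lag=lo,
    )
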