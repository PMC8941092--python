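"""Topo-climatic predictability of reburns via random forests with
conditional permutation importance.

A classification forest separates single-fire from reburn (2+ fire) points
on bioclimatic and terrain covariates.  Variable importance is the
permutation-based mean decrease in held-out accuracy, computed
*conditionally*: a predictor is permuted within strata built from the
cross-classification of quantile bins of its significantly correlated
covariates, so that shared variance with correlated predictors is not
credited to it.  With no correlated covariates (or ``alpha=0``) this
reduces exactly to ordinary marginal permutation importance.  Stability of
accuracy and importance is assessed by replicating the forest under
different seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

LABEL_COL = "fires"
DEFAULT_N_TREES = 1_000
DEFAULT_N_FORESTS = 20
DEFAULT_ALPHA = 0.05
DEFAULT_N_BINS = 4
#: Reduce conditioning bins until the median stratum holds at least this many rows.
MIN_MEDIAN_STRATUM = 10

VARIABLE_GROUPS = {
    "precipitation": lambda v: "Precip" in v and "Seasonality" not in v,
    "temperature": lambda v: ("Temp" in v and "Seasonality" not in v),
    "variability": lambda v: "Seasonality" in v,
    "topography": lambda v: v.lower() in {"slope", "aspect", "elev", "elevation"},
}


def variable_group(name: str) -> str:
    for group, pred in VARIABLE_GROUPS.items():
        if pred(name):
            return group
    return "other"


def transform_aspect(aspect) -> np.ndarray | float:
    """Fold compass aspect (degrees) onto a 0-1 heat-load-style scale:
    (cos(45 deg - aspect) + 1)/2, so NE-facing slopes score 1 and
    SW-facing slopes 0.  Flat cells (NaN) map to the neutral 0.5."""
    a = np.asarray(aspect, dtype=float)
    flat = np.isnan(a)
    valid = a[~flat]
    if ((valid < 0) | (valid >= 360)).any():
        raise ValueError("aspect must lie in [0, 360) degrees (NaN = flat)")
    out = (np.cos(np.radians(45.0 - a)) + 1.0) / 2.0
    out = np.where(flat, 0.5, out)
    return float(out) if np.isscalar(aspect) or np.ndim(aspect) == 0 else out


def split_train_test(
    data: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_col: str = LABEL_COL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label train/test split, deterministic in seed."""
    labels = data[label_col]
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to split")
    if test_fraction == 0:
        warnings.warn("test_fraction=0: returning an empty test set")
        return data.copy(), data.iloc[0:0].copy()
    train, test = train_test_split(
        data,
        test_size=test_fraction,
        stratify=labels,
        random_state=int(seed) % (2**32),
    )
    return train, test


def balance_classes(
    data: pd.DataFrame, seed: int = 0, label_col: str = LABEL_COL
) -> pd.DataFrame:
    """Downsample the majority class to parity (for training)."""
    rng = np.random.default_rng(seed)
    groups = [g for _, g in data.groupby(label_col)]
    n_min = min(len(g) for g in groups)
    parts = []
    for g in groups:
        if len(g) > n_min:
            keep = rng.choice(len(g), n_min, replace=False)
            g = g.iloc[np.sort(keep)]
        parts.append(g)
    return pd.concat(parts)


@dataclass
class ForestModel:
    clf: RandomForestClassifier
    features: list[str]
    label_col: str
    oob_accuracy: float

    def accuracy(self, data: pd.DataFrame) -> float:
        X = data[self.features].to_numpy()
        y = data[self.label_col].to_numpy()
        return float((self.clf.predict(X) == y).mean())


def fit_forest(
    train: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    label_col: str = LABEL_COL,
) -> ForestModel:
    """Fit a classification forest; reports out-of-bag accuracy."""
    features = [c for c in train.columns if c != label_col]
    y = train[label_col]
    if y.nunique() < 2:
        raise ValueError("training data contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    clf.fit(train[features].to_numpy(), y.to_numpy())
    return ForestModel(
        clf=clf,
        features=features,
        label_col=label_col,
        oob_accuracy=float(clf.oob_score_),
    )


def correlated_set(
    features: pd.DataFrame, target: str, alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Names of the other variables whose linear correlation with ``target``
    is significant at ``alpha`` (these become the conditioning variables).
    ``alpha=0`` always returns the empty set (marginal importance)."""
    if features.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if alpha <= 0:
        return []
    x = features[target].to_numpy()
    if np.ptp(x) == 0:
        warnings.warn(f"target column {target!r} is constant; no conditioning")
        return []
    out = []
    for col in features.columns:
        if col == target:
            continue
        y = features[col].to_numpy()
        if np.ptp(y) == 0:
            warnings.warn(f"constant column {col!r} excluded from conditioning")
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            out.append(col)
    return out


def _strata_labels(
    features: pd.DataFrame, conditioning: Sequence[str], n_bins: int
) -> np.ndarray:
    """Cross-classification of quantile bins of the conditioning variables,
    coarsened until the median stratum holds MIN_MEDIAN_STRATUM rows."""
    n = len(features)
    if not conditioning:
        return np.zeros(n, dtype=int)
    bins = n_bins
    while True:
        codes = np.zeros(n, dtype=np.int64)
        for col in conditioning:
            vals = features[col].to_numpy()
            edges = np.quantile(vals, np.linspace(0, 1, bins + 1)[1:-1])
            codes = codes * (bins + 1) + np.searchsorted(edges, vals, side="right")
        _, labels, counts = np.unique(codes, return_inverse=True, return_counts=True)
        if bins == 1 or np.median(counts) >= MIN_MEDIAN_STRATUM:
            return labels
        bins -= 1


DEFAULT_PERM_REPS = 4


def conditional_importance(
    model: ForestModel,
    data: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_bins: int = DEFAULT_N_BINS,
    reps: int = DEFAULT_PERM_REPS,
    seed: int = 0,
) -> dict[str, float]:
    """Per-variable conditional mean decrease in accuracy on ``data``.

    Each variable is permuted (``reps`` times) within the strata given by
    quantile bins of its correlated covariates; importance is the drop in
    accuracy relative to the unpermuted data, averaged over repetitions.
    Strata with a single row are left unpermuted; if every stratum is a
    singleton the variable falls back to marginal permutation with a
    warning.  All permuted matrices are scored in one batched forest
    prediction.
    """
    rng = np.random.default_rng(seed)
    features = data[model.features]
    n = len(features)
    y = data[model.label_col].to_numpy()
    X0 = features.to_numpy(dtype=float)
    base_acc = float((model.clf.predict(X0) == y).mean())
    permuted: list[np.ndarray] = []
    for j, var in enumerate(model.features):
        cond = correlated_set(features, var, alpha)
        labels = _strata_labels(features, cond, n_bins)
        _, counts = np.unique(labels, return_counts=True)
        if cond and (counts <= 1).all():
            warnings.warn(
                f"all conditioning strata for {var!r} are singletons; "
                "falling back to marginal permutation"
            )
            labels = np.zeros(n, dtype=int)
        for _ in range(reps):
            Xp = X0.copy()
            col = Xp[:, j].copy()
            for s in np.unique(labels):
                idx = np.flatnonzero(labels == s)
                if idx.size >= 2:
                    col[idx] = col[idx[rng.permutation(idx.size)]]
            Xp[:, j] = col
            permuted.append(Xp)
    preds = model.clf.predict(np.vstack(permuted))
    importances: dict[str, float] = {}
    for j, var in enumerate(model.features):
        drops = [
            base_acc - float((preds[(j * reps + r) * n : (j * reps + r + 1) * n] == y).mean())
            for r in range(reps)
        ]
        importances[var] = float(np.mean(drops))
    return importances


@dataclass
class ImportanceResult:
    """Importance and accuracy across repeated forests."""

    importances: pd.DataFrame  # rows: forests, columns: variables
    test_accuracy: np.ndarray
    oob_accuracy: np.ndarray
    n_trees: int
    alpha: float
    n_bins: int
    params: dict = field(default_factory=dict)

    @property
    def n_forests(self) -> int:
        return len(self.importances)


def run_importance_forests(
    data: pd.DataFrame,
    n_forests: int = DEFAULT_N_FORESTS,
    n_trees: int = DEFAULT_N_TREES,
    test_fraction: float = 0.2,
    alpha: float = DEFAULT_ALPHA,
    n_bins: int = DEFAULT_N_BINS,
    reps: int = DEFAULT_PERM_REPS,
    seed: int = 0,
    balance: bool = True,
    label_col: str = LABEL_COL,
) -> ImportanceResult:
    """Grow ``n_forests`` independently seeded forests on one stratified
    train/test split, recording held-out accuracy and conditional
    importance per forest.  The majority class is downsampled to parity in
    training by default (configurable off)."""
    master = np.random.default_rng(seed)
    split_seed, balance_seed = master.integers(0, 2**31 - 1, size=2)
    forest_seeds = master.integers(0, 2**31 - 1, size=n_forests)
    perm_seeds = master.integers(0, 2**31 - 1, size=n_forests)
    train, test = split_train_test(data, test_fraction, split_seed, label_col)
    if balance:
        train = balance_classes(train, balance_seed, label_col)
    rows, acc, oob = [], [], []
    for i in range(n_forests):
        model = fit_forest(train, n_trees, forest_seeds[i], label_col)
        acc.append(model.accuracy(test))
        oob.append(model.oob_accuracy)
        rows.append(
            conditional_importance(model, test, alpha, n_bins, reps, perm_seeds[i])
        )
    return ImportanceResult(
        importances=pd.DataFrame(rows),
        test_accuracy=np.asarray(acc),
        oob_accuracy=np.asarray(oob),
        n_trees=n_trees,
        alpha=alpha,
        n_bins=n_bins,
        params={"n_forests": n_forests, "reps": reps, "balance": balance,
                "test_fraction": test_fraction, "seed": seed},
    )


def importance_report(result: ImportanceResult) -> pd.DataFrame:
    """Variables ordered by median importance (descending; ties keep input
    order), with quartiles and broad driver-group tags."""
    imp = result.importances
    med = imp.median()
    order = np.argsort(-med.to_numpy(), kind="stable")
    cols = imp.columns[order]
    return pd.DataFrame(
        {
            "median": med[cols],
            "q25": imp[cols].quantile(0.25),
            "q75": imp[cols].quantile(0.75),
            "group": [variable_group(c) for c in cols],
        },
        index=pd.Index(cols, name="variable"),
    )
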