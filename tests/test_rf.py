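"""Aspect transform, stratified splitting, forests, and conditional
permutation importance."""

import numpy as np
import pandas as pd
import pytest

from reburnscape import rf
from reburnscape import synthetic as syn


class TestTransformAspect:
    @pytest.mark.parametrize("deg,val", [(45.0, 1.0), (225.0, 0.0), (135.0, 0.5)])
    def test_folded_scale(self, deg, val):
        assert rf.transform_aspect(deg) == pytest.approx(val, abs=1e-12)

    def test_flat_cells_are_neutral(self):
        assert rf.transform_aspect(float("nan")) == 0.5

    @pytest.mark.parametrize("bad", [-5.0, 360.0, 400.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            rf.transform_aspect(bad)

    def test_range_is_unit_interval(self):
        vals = rf.transform_aspect(np.arange(0.0, 360.0, 7.0))
        assert vals.min() >= 0.0 and vals.max() <= 1.0


def _labelled(n, seed=0, signal=False):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    if signal:
        label = (x > 0).astype(int) + 1
    else:
        label = rng.integers(1, 3, n)
    return pd.DataFrame({"a": x, "b": noise, rf.LABEL_COL: label})


class TestSplit:
    def test_published_partition_arithmetic(self):
        """2,816 rows at 20% test -> 564 test / 2,252 train."""
        df = _labelled(2816, seed=1)
        train, test = rf.split_train_test(df, 0.2, seed=0)
        assert (len(train), len(test)) == (2252, 564)
        assert set(train.index).isdisjoint(test.index)

    def test_stratification_preserves_class_balance(self):
        df = _labelled(1000, seed=2)
        train, test = rf.split_train_test(df, 0.2, seed=0)
        p_all = (df[rf.LABEL_COL] == 2).mean()
        assert (test[rf.LABEL_COL] == 2).mean() == pytest.approx(p_all, abs=0.02)

    def test_deterministic_given_seed(self):
        df = _labelled(500, seed=3)
        a = rf.split_train_test(df, 0.2, seed=11)[1]
        b = rf.split_train_test(df, 0.2, seed=11)[1]
        assert a.equals(b)

    def test_zero_fraction_warns_empty_test(self):
        with pytest.warns(UserWarning):
            _, test = rf.split_train_test(_labelled(50), 0.0, seed=0)
        assert len(test) == 0

    def test_single_class_rejected(self):
        df = _labelled(50, seed=4)
        df[rf.LABEL_COL] = 1
        with pytest.raises(ValueError):
            rf.split_train_test(df, 0.2, seed=0)


class TestFitForest:
    def test_deterministic_signal_is_learned(self):
        df = _labelled(600, seed=5, signal=True)
        train, test = rf.split_train_test(df, 0.2, seed=0)
        model = rf.fit_forest(train, n_trees=100, seed=0)
        assert model.accuracy(test) > 0.95
        assert model.oob_accuracy > 0.9

    def test_no_signal_gives_chance_accuracy(self):
        df = _labelled(600, seed=6, signal=False)
        train, test = rf.split_train_test(df, 0.2, seed=0)
        model = rf.fit_forest(train, n_trees=100, seed=0)
        majority = test[rf.LABEL_COL].value_counts(normalize=True).max()
        assert model.accuracy(test) <= majority + 0.12

    def test_single_class_train_rejected(self):
        df = _labelled(50, seed=7)
        df[rf.LABEL_COL] = 2
        with pytest.raises(ValueError):
            rf.fit_forest(df, n_trees=10, seed=0)


class TestCorrelatedSet:
    def test_duplicated_column_always_included(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        feats = pd.DataFrame({"a": x, "a_copy": x, "b": rng.standard_normal(100)})
        assert "a_copy" in rf.correlated_set(feats, "a")

    def test_alpha_zero_is_marginal(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        assert rf.correlated_set(feats, "a", alpha=0.0) == []

    def test_independent_columns_rarely_condition(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            feats = pd.DataFrame(
                {"a": rng.standard_normal(2000), "b": rng.standard_normal(2000)}
            )
            hits += len(rf.correlated_set(feats, "a"))
        assert hits <= 5  # ~5% type-I rate

    def test_constant_column_excluded_with_warning(self):
        feats = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning):
            assert rf.correlated_set(feats, "a") == []


class TestConditionalImportance:
    def _fitted(self, n=1200, seed=0, twin=True):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        cols = {"signal": x}
        if twin:
            cols["twin"] = x  # perfectly correlated duplicate
        cols["noise"] = rng.standard_normal(n)
        cols[rf.LABEL_COL] = (x + 0.6 * rng.standard_normal(n) > 0).astype(int) + 1
        df = pd.DataFrame(cols)
        train, test = rf.split_train_test(df, 0.3, seed=1)
        return rf.fit_forest(train, n_trees=150, seed=2), test

    def test_noise_importance_near_zero_signal_ranks_first(self):
        """With a single informative predictor and independent noise the
        informative one dominates the conditional ranking."""
        model, test = self._fitted(twin=False)
        imp = rf.conditional_importance(model, test, seed=3)
        assert abs(imp["noise"]) < 0.03
        assert imp["signal"] > imp["noise"] + 0.05

    def test_duplicated_predictor_conditional_below_marginal(self):
        model, test = self._fitted()
        cond = rf.conditional_importance(model, test, alpha=0.05, seed=4)
        marg = rf.conditional_importance(model, test, alpha=0.0, seed=4)
        assert cond["signal"] < marg["signal"]
        assert cond["twin"] < marg["twin"]

    def test_alpha_zero_equals_marginal_permutations_exactly(self):
        model, test = self._fitted(n=400, seed=5)
        only_noise = test[["noise", "signal", "twin", rf.LABEL_COL]]
        a = rf.conditional_importance(model, only_noise, alpha=0.0, seed=6)
        b = rf.conditional_importance(model, only_noise, alpha=0.0, seed=6)
        assert a == b  # same seed, same permutations, bit-identical

    def test_stratified_permutation_preserves_stratum_multisets(self):
        rng = np.random.default_rng(7)
        feats = pd.DataFrame({"v": rng.standard_normal(200),
                              "c": rng.standard_normal(200)})
        labels = rf._strata_labels(feats, ["c"], n_bins=4)
        col = feats["v"].to_numpy().copy()
        for s in np.unique(labels):
            idx = np.flatnonzero(labels == s)
            if idx.size >= 2:
                col[idx] = col[idx[rng.permutation(idx.size)]]
        for s in np.unique(labels):
            idx = labels == s
            assert sorted(col[idx]) == sorted(feats["v"].to_numpy()[idx])

    def test_strata_median_size_floor(self):
        rng = np.random.default_rng(8)
        feats = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        labels = rf._strata_labels(feats, ["b", "c"], n_bins=4)
        _, counts = np.unique(labels, return_counts=True)
        assert np.median(counts) >= rf.MIN_MEDIAN_STRATUM or len(counts) == 1


class TestImportanceReport:
    def test_single_forest_medians_are_values(self):
        df = syn.make_classification_table(n=400, seed=0)
        res = rf.run_importance_forests(df, n_forests=1, n_trees=50, seed=0)
        report = rf.importance_report(res)
        assert np.allclose(
            report["median"].to_numpy(),
            res.importances.iloc[0][report.index].to_numpy(),
        )

    def test_all_zero_ties_keep_input_order(self):
        res = rf.ImportanceResult(
            importances=pd.DataFrame([{"b": 0.0, "a": 0.0, "c": 0.0}]),
            test_accuracy=np.array([0.5]),
            oob_accuracy=np.array([0.5]),
            n_trees=1, alpha=0.05, n_bins=4,
        )
        assert list(rf.importance_report(res).index) == ["b", "a", "c"]

    def test_group_tags(self):
        assert rf.variable_group("PrecipColdestQ") == "precipitation"
        assert rf.variable_group("TempSeasonality") == "variability"
        assert rf.variable_group("slope") == "topography"
        assert rf.variable_group("TempWarmestQ") == "temperature"

    def test_repeat_run_bit_identical(self):
        df = syn.make_classification_table(n=300, seed=2)
        a = rf.run_importance_forests(df, n_forests=2, n_trees=30, seed=9)
        b = rf.run_importance_forests(df, n_forests=2, n_trees=30, seed=9)
        assert a.importances.equals(b.importances)
        assert np.array_equal(a.test_accuracy, b.test_accuracy)
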