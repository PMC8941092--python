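"""Synthetic landscape generator: determinism, refractory feedback,
burn-fraction targeting, and format round trips."""

import numpy as np
import pytest

from reburnscape import fire_history as fh
from reburnscape import synthetic as syn


def _small_config(**kw):
    defaults = dict(
        grid_shape=(40, 40),
        cell_size=100.0,
        years=tuple(range(2000, 2012)),
        burn_fraction=0.03,
        n_fires_per_year=4,
        seed=7,
    )
    defaults.update(kw)
    return syn.SimConfig(**defaults)


class TestMakeLandscape:
    def test_deterministic_under_seed(self):
        cfg = _small_config()
        a, b = syn.make_landscape(cfg), syn.make_landscape(cfg)
        assert np.array_equal(a.cover, b.cover)
        for k in a.covariates:
            assert np.array_equal(
                a.covariates[k], b.covariates[k], equal_nan=True
            )

    def test_single_class_cover_is_uniform(self):
        cfg = _small_config(cover_weights={"coniferous": 1.0})
        ls = syn.make_landscape(cfg)
        assert (ls.cover == 0).all() and ls.classes == ("coniferous",)

    def test_cover_shape_matches_grid(self):
        ls = syn.make_landscape(_small_config(grid_shape=(50, 50)))
        assert ls.cover.shape == (50, 50)

    def test_cover_is_patchy_not_iid(self):
        """Neighbouring cells agree far more often than class frequencies
        would predict under independence."""
        ls = syn.make_landscape(_small_config(grid_shape=(60, 60)))
        same = (ls.cover[:, 1:] == ls.cover[:, :-1]).mean()
        freqs = np.bincount(ls.cover.ravel()) / ls.cover.size
        iid_rate = (freqs**2).sum()
        assert same > iid_rate + 0.3

    def test_empty_cover_weights_rejected(self):
        with pytest.raises(ValueError):
            _small_config(cover_weights={})

    def test_covariate_fields_are_smooth(self):
        ls = syn.make_landscape(_small_config())
        f = ls.covariates["AnnualPrecip"]
        lag1 = np.corrcoef(f[:, 1:].ravel(), f[:, :-1].ravel())[0, 1]
        assert lag1 > 0.8


class TestSimulateFireHistory:
    def test_deterministic_under_seed(self):
        cfg = _small_config()
        m1 = syn.simulate_fire_history(syn.make_landscape(cfg))
        m2 = syn.simulate_fire_history(syn.make_landscape(cfg))
        assert np.array_equal(m1, m2)

    def test_full_suppression_blocks_reburn_within_tau(self):
        """rho=0: a burned cell cannot burn again for tau years."""
        cfg = _small_config(refractory_rho=0.0, refractory_tau=10, seed=3)
        masks = syn.simulate_fire_history(syn.make_landscape(cfg))
        n_years = masks.shape[0]
        for t in range(n_years):
            horizon = masks[t + 1 : t + 11]
            assert not (horizon & masks[t]).any()

    def test_burn_fraction_near_target(self):
        cfg = _small_config(refractory_rho=1.0, burn_fraction=0.05)
        masks = syn.simulate_fire_history(syn.make_landscape(cfg))
        fracs = masks.mean(axis=(1, 2))
        assert np.allclose(fracs, 0.05, rtol=0.2)

    def test_zero_burn_fraction_gives_empty_masks(self):
        cfg = _small_config(burn_fraction=0.0)
        masks = syn.simulate_fire_history(syn.make_landscape(cfg))
        assert not masks.any()

    def test_fires_are_contiguous_clusters(self):
        """A single fire's footprint is 4-connected."""
        from scipy import ndimage

        cfg = _small_config(n_fires_per_year=1, burn_fraction=0.04, seed=5)
        masks = syn.simulate_fire_history(syn.make_landscape(cfg))
        for mask in masks:
            _, n_components = ndimage.label(mask)
            assert n_components == 1

    def test_no_feedback_overlap_matches_random_expectation(self):
        """rho=1, uniform cover: mean overlap of consecutive burn-year sets
        approaches the random-placement closed form n1*n2/N."""
        overlaps, expected = [], []
        for seed in range(40):
            cfg = _small_config(
                cover_weights={"coniferous": 1.0},
                refractory_rho=1.0,
                refractory_tau=10,
                years=(2000, 2001),
                burn_fraction=0.05,
                seed=seed,
            )
            masks = syn.simulate_fire_history(syn.make_landscape(cfg))
            n1, n2 = masks[0].sum(), masks[1].sum()
            overlaps.append((masks[0] & masks[1]).sum())
            expected.append(n1 * n2 / masks[0].size)
        diff = np.mean(overlaps) - np.mean(expected)
        se = np.std(overlaps, ddof=1) / np.sqrt(len(overlaps))
        assert abs(diff) <= 3 * max(se, 1e-9)

    def test_conifer_weight_raises_conifer_share_of_burns(self):
        """Burned area shifts toward conifer cover as its weight grows."""
        shares = {}
        for w in (0.3, 3.0):
            vals = []
            for seed in range(10):
                cfg = _small_config(
                    cover_weights={**syn.DEFAULT_COVER_WEIGHTS, "coniferous": w},
                    seed=seed,
                )
                ls = syn.make_landscape(cfg)
                masks = syn.simulate_fire_history(ls)
                burned = masks.sum(axis=0) > 0
                vals.append((ls.cover[burned] == 0).mean())
            shares[w] = np.mean(vals)
        assert shares[3.0] > shares[0.3]


class TestWriteHistory:
    def test_round_trip_recovers_masks_exactly(self, tmp_path):
        cfg = _small_config()
        ls = syn.make_landscape(cfg)
        masks = syn.simulate_fire_history(ls)
        syn.write_history(ls, tmp_path)
        stack = fh.read_severity_stack(tmp_path)
        # severity encoding: burned -> 3, unburned -> 1
        assert set(np.unique(stack.grids)) <= {1, 3}
        recovered = np.stack([fh.classify_burned(g) for g in stack.grids])
        assert np.array_equal(recovered, masks)

    def test_covariate_csv_row_count(self, tmp_path):
        cfg = _small_config()
        ls = syn.make_landscape(cfg)
        syn.simulate_fire_history(ls)
        info = syn.write_history(ls, tmp_path, spacing=400.0)
        import pandas as pd

        df = pd.read_csv(info["covariates"])
        assert len(df) == info["n_points"] == 100  # (4000/400)^2


class TestClassificationTable:
    def test_bayes_accuracy_inversion(self):
        beta = syn.beta_for_bayes_accuracy(0.8)
        assert syn.bayes_accuracy(beta) == pytest.approx(0.8, abs=1e-9)
        assert syn.bayes_accuracy(0.0) == pytest.approx(0.5, abs=1e-9)

    def test_table_structure_and_signal(self):
        df = syn.make_classification_table(n=5000, seed=1)
        assert set(df["fires"]) == {1, 2}
        assert df["fires"].mean() - 1 == pytest.approx(0.5, abs=0.05)
        # precipitation variables correlate with the label, topography does not
        y = df["fires"].to_numpy()
        r_precip = abs(np.corrcoef(df["PrecipDriestQ"], y)[0, 1])
        r_topo = abs(np.corrcoef(df["elev"], y)[0, 1])
        assert r_precip > 0.2 > r_topo

    def test_deterministic(self):
        a = syn.make_classification_table(n=200, seed=4)
        b = syn.make_classification_table(n=200, seed=4)
        assert a.equals(b)
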