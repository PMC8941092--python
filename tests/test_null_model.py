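"""Observed moving-window reburn proportions and the randomized null."""

import numpy as np
import pytest

from reburnscape import null_model as nm
from reburnscape.fire_history import BurnHistory


def _points(burn_years_per_point):
    return [
        BurnHistory(point_id=i, burn_years=tuple(y))
        for i, y in enumerate(burn_years_per_point)
    ]


class TestObservedWindowReburn:
    RECORD = range(1984, 2017)

    def test_worked_example(self):
        """10 points: 4 burned in window, 2 in focal year, 1 overlapping."""
        h = _points(
            [(1990,), (1991,), (1992,), (1993, 2000), (2000,)]
            + [()] * 5
        )
        spec = nm.WindowSpec(window_length=10, focal_year=2000)
        obs = nm.observed_window_reburn(h, spec, self.RECORD)
        assert obs.proportion == pytest.approx(0.5)
        assert (obs.n_window_burned, obs.n_focal_burned) == (4, 2)

    def test_no_overlap_is_zero(self):
        h = _points([(1990,), (2000,), ()])
        spec = nm.WindowSpec(window_length=5, focal_year=2000)
        assert nm.observed_window_reburn(h, spec, self.RECORD).proportion == 0.0

    def test_full_overlap_is_one(self):
        h = _points([(1995, 2000), (1996, 2000), ()])
        spec = nm.WindowSpec(window_length=10, focal_year=2000)
        assert nm.observed_window_reburn(h, spec, self.RECORD).proportion == 1.0

    def test_undefined_when_no_focal_burns(self):
        h = _points([(1990,), ()])
        spec = nm.WindowSpec(window_length=10, focal_year=2000)
        obs = nm.observed_window_reburn(h, spec, self.RECORD)
        assert not obs.defined and np.isnan(obs.proportion)

    def test_window_before_record_rejected(self):
        h = _points([(1990,)])
        spec = nm.WindowSpec(window_length=10, focal_year=1990)
        with pytest.raises(ValueError, match="record start"):
            nm.observed_window_reburn(h, spec, self.RECORD)


class TestClosedForm:
    def test_worked_example(self):
        count, prop = nm.expected_overlap_closed_form(1000, 200, 100)
        assert count == pytest.approx(20.0) and prop == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "N,n1,n2,count,prop",
        [(500, 0, 100, 0.0, 0.0), (500, 500, 100, 100.0, 1.0)],
    )
    def test_degenerate_margins(self, N, n1, n2, count, prop):
        assert nm.expected_overlap_closed_form(N, n1, n2) == (count, prop)

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            nm.expected_overlap_closed_form(0, 0, 0)

    def test_brute_force_enumeration_oracle(self):
        """Exhaustive enumeration of all subset pairs on a tiny lattice
        reproduces n1*n2/N."""
        from itertools import combinations

        N, n1, n2 = 6, 3, 2
        overlaps = [
            len(set(a) & set(b))
            for a in combinations(range(N), n1)
            for b in combinations(range(N), n2)
        ]
        assert np.mean(overlaps) == pytest.approx(n1 * n2 / N)


class TestNullDistribution:
    def test_zero_window_burn_gives_exact_zero(self):
        res = nm.null_reburn_distribution(500, 0, 100, reps=500, seed=1)
        assert res.mean == 0.0 and res.q95 == 0.0

    def test_saturated_window_gives_exact_one(self):
        res = nm.null_reburn_distribution(500, 500, 100, reps=500, seed=1)
        assert res.mean == 1.0 and res.q05 == 1.0

    def test_monte_carlo_mean_matches_closed_form(self):
        res = nm.null_reburn_distribution(
            1000, 200, 100, reps=10_000, seed=2, keep_draws=True
        )
        se = res.draws.std(ddof=1) / np.sqrt(res.reps)
        assert abs(res.mean - 0.2) <= 3 * se

    def test_subset_sampler_agrees_with_hypergeometric(self):
        """The literal two-subset draw and the direct overlap sampler are
        the same distribution (means/sds within Monte-Carlo error)."""
        a = nm.null_reburn_distribution(
            200, 40, 20, reps=4000, seed=3, method="hypergeometric", keep_draws=True
        )
        b = nm.null_reburn_distribution(
            200, 40, 20, reps=4000, seed=3, method="subsets", keep_draws=True
        )
        se = np.hypot(a.draws.std() / 63, b.draws.std() / 63)
        assert abs(a.mean - b.mean) <= 3 * se
        assert a.draws.std() == pytest.approx(b.draws.std(), rel=0.15)

    def test_undefined_focal_flagged(self):
        res = nm.null_reburn_distribution(100, 10, 0, reps=100, seed=0)
        assert not res.defined and np.isnan(res.mean)

    def test_fixed_seed_bit_identical(self):
        a = nm.null_reburn_distribution(300, 60, 30, reps=1000, seed=9, keep_draws=True)
        b = nm.null_reburn_distribution(300, 60, 30, reps=1000, seed=9, keep_draws=True)
        assert np.array_equal(a.draws, b.draws)

    def test_mean_increases_with_n1_invariant_to_n2(self):
        means_n1 = [
            nm.null_reburn_distribution(400, n1, 40, reps=6000, seed=5).mean
            for n1 in (40, 120, 240)
        ]
        assert means_n1 == sorted(means_n1)
        m1 = nm.null_reburn_distribution(400, 120, 20, reps=20_000, seed=6).mean
        m2 = nm.null_reburn_distribution(400, 120, 80, reps=20_000, seed=7).mean
        assert m1 == pytest.approx(m2, abs=0.02)  # both estimate n1/N = 0.3


class TestSeriesLayouts:
    RECORD = range(1984, 2017)

    def _histories(self):
        rng = np.random.default_rng(0)
        out = []
        for i in range(300):
            years = sorted(
                set(rng.choice(np.arange(1984, 2017), rng.poisson(1.2), replace=False))
            )
            out.append(BurnHistory(point_id=i, burn_years=tuple(int(y) for y in years)))
        return out

    def test_window_fit_arithmetic(self):
        h = self._histories()
        assert len(nm.window_series(h, 10, self.RECORD, reps=50, seed=0)) == 23
        assert len(nm.window_series(h, 20, self.RECORD, reps=50, seed=0)) == 13

    def test_no_fires_all_undefined(self):
        h = _points([()] * 20)
        series = nm.window_series(h, 10, self.RECORD, reps=50, seed=0)
        assert not series["defined"].any()

    def test_band_with_lo_zero_matches_window_series(self):
        h = self._histories()
        a = nm.interval_band_series(h, 0, 10, self.RECORD, reps=200, seed=4)
        b = nm.window_series(h, 10, self.RECORD, reps=200, seed=4)
        assert a.drop(columns="lag").equals(b.drop(columns="lag"))

    def test_band_window_years_definition(self):
        spec = nm.WindowSpec(window_length=10, focal_year=2010, lag=10)
        assert list(spec.window_years) == list(range(1990, 2000))

    def test_band_beyond_record_rejected(self):
        with pytest.raises(ValueError):
            nm.interval_band_series(
                self._histories(), 10, 50, self.RECORD, reps=10, seed=0
            )

    def test_null_conditioned_on_each_years_margins(self):
        h = self._histories()
        series = nm.window_series(h, 10, self.RECORD, reps=3000, seed=1)
        ok = series.dropna(subset=["null_mean"])
        # null mean tracks that year's n1/N closed form
        assert np.allclose(ok["null_mean"], ok["n1"] / ok["N"], atol=0.02)
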