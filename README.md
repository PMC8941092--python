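# reburnscape

Short-interval fire ("reburn") dynamics in boreal landscapes: how often the
same ground burns twice within a decade or two, whether recently burned
stands suppress reburning (fire self-regulation), which cover types absorb
the reburns, and whether reburn locations are climatically predictable.

The package is a library for landscape fire ecologists working with annual
burn-severity rasters (MTBS-style integer severity classes) and point
covariate tables. It reduces a multi-year raster stack to per-point
burn-year histories on a uniform sampling lattice and runs four analyses on
them, each exercisable end to end on a bundled synthetic fire-landscape
simulator so that every stage is testable without external data.

## The statistics at the core

**Reburn accounting.** A point with burn years `y_1 < y_2 < ...` contributes
the intervals `y_{k+1} - y_k`. Reburn percentage is the fraction of burned
points with 2+ burns; interval distributions are reported as an ECDF
truncated at 16 years (longer intervals have less opportunity to be
observed in a ~30-year record) and as upper-tail fractions.

**Randomized-placement null model.** For focal year *t* and window length
*W*, the observed reburn proportion is

    p_obs(t) = |B_t ∩ (B_{t-W} ∪ ... ∪ B_{t-1})| / |B_t|

where `B_y` is the set of points burned in year *y*. The null re-places the
window-burned count `n1` and the focal count `n2` uniformly at random over
the `N` lattice points (no spatial interaction) and records the overlap
proportion, repeated 10,000 times. The overlap count is exactly
Hypergeometric(N, n1, n2), so the null mean is `n1/N` — an analytic check
carried in the test suite. Observed proportions sitting below the null band
indicate a negative (refractory) feedback of recent burns on reburning.

**Trends.** Observed and null series are tested for short-term
autocorrelation (Box–Pierce, `Q = n Σ r_k²` against χ²_h) and their trends
estimated with the Theil–Sen slope (median of all pairwise slopes, with the
classical rank-based 5th/95th confidence bounds and a bootstrap SE). The
conifer share of reburns per year is fitted by least squares weighted by
the number of reburn events in that year.

**Predictability.** A random-forest classifier separates single-fire from
reburn points on bioclimatic and terrain covariates; drivers are ranked by
*conditional* permutation importance — each variable is permuted within
strata built from quantile bins of its significantly correlated covariates,
so shared variance among correlated climate variables is not credited to
any one of them. Stability is assessed over 20 independently seeded
forests.

**Synthetic landscapes.** Fires are grown as weighted clusters on a cover
mosaic (five classes of differing flammability) with a refractory feedback:
for `tau` years after a cell burns, its selection weight is multiplied by
`rho` (`rho=0` full suppression, `rho=1` no feedback). Covariate fields are
smooth random cosine surfaces; everything is deterministic given a seed.

## Worked example

Simulate a 33-year record with the default first-decade refractory feedback
(`tau=10`, `rho=0.1`), sample a 2 km lattice and test for self-regulation
(see `examples/02_reburn_statistics.py` and
`examples/03_null_model_feedback.py`):

```
23.4% of 2500 points burned;
of those, 92.6% burned once, 7.0% twice, 0.3% three+ times
45 fire intervals (14 longer than 16 yr not in the ECDF)
intervals >= 5 yr: 88.9%;  >= 10 yr: 80.0%

23 focal years; observed reburn proportion sits below the null 25th
percentile in 48% of them
observed trend: 0.000%/yr (5th/95th CI -0.194 to 0.000)
null trend:     0.211%/yr (5th/95th CI 0.205 to 0.218)
```

Read: about a fifth of the landscape burned and only ~7% of burned points
reburned, almost never within 10 years of the first fire. Fires increase
over the record, so the null expectation of ≤10-yr reburning rises at
0.21%/yr — but the observed proportion stays flat at zero: the refractory
feedback visibly decouples reburning from the rising fire load. Each script
in `examples/` demonstrates one capability this way (simulation, interval
statistics, the null model, cover-type trends, predictability).

A thin CLI wraps the same functions for shell use:

```bash
reburnscape simulate --seed 1 --out record/
reburnscape sample --rasters record/ --spacing 2000 --threshold 2 --out hist.csv
reburnscape nullmodel --histories hist.csv --window 10 --reps 10000 --seed 42 --out w10.csv
reburnscape run --config run.yaml --out results/    # full pipeline + manifest
```

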