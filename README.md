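# dissimogram

Estimate the degree of **randomness in community composition** from
spatially referenced survey data.

Community ecologists often ask how much of the variation in species
composition between sites is driven by deterministic, spatially structured
processes (environmental filtering, dispersal limitation) versus chance.
This package implements a distance-decay approach to that question: the
Jaccard dissimilarity between every pair of sites is regressed on the
geographic distance between them with a non-linear curve (a
*dissimogram*, the compositional analogue of a variogram), and the curve's
y-intercept — the **nugget** — is read as the dissimilarity that remains
at zero spatial distance, i.e. the fraction of composition that the
spatially autocorrelated environment cannot explain.

It is written for analyses of repeated point-count surveys (the motivating
case is forest bird communities surveyed in several regions over several
years), but the machinery applies to any site-by-species incidence data
with projected coordinates — including microbiome-style beta-diversity
distance-decay analyses.

## Model

For sites a distance *d* (metres) apart, pairwise Jaccard dissimilarity
1 − D′ (with D′ = |A∩B|/|A∪B|) is fitted by non-linear least squares with
one of two three-parameter families:

* **Gompertz**: D′(d) = a · e^(−b · e^(−c·d)) — nugget a·e^(−b), asymptote a
* **Negative exponential**: D′(d) = a − b·e^(−c·d) — nugget a − b, asymptote a

Parameters are estimated with the Gauss–Newton algorithm (Levenberg-style
damping, multi-start initialisation). Goodness of fit is the pseudo-R²
(squared Pearson correlation of fitted vs observed values). Nuggets
outside [0, 1] flag a poorly fitting model and are reported "n/a".

Supporting components:

* survey ingestion and aggregation (max count over rounds, presence
  rules, cumulative composition across years, aerial-species exclusion);
* stratification by management intensity (regional median split) and by
  inter-annual species turnover (60/70/80% cut-offs);
* occupancy–detection models (static and dynamic multi-season
  likelihoods) for per-species detectability ψ;
* a synthetic metacommunity generator with a tunable randomness fraction
  ρ that mixes niche-driven and spatially random occupancy, used to
  validate that the nugget/asymptote ratio actually ranks the generating
  randomness.

## Worked example

```python
from dissimogram import (SimConfig, simulate_metacommunity,
                         presence_by_year, build_pair_table, Dissimogram)

cfg = SimConfig(seed=7, n_regions=1, rho=0.4, detection_p=0.9)
surveys, plots, truth = simulate_metacommunity(cfg)

per_year = presence_by_year(surveys, plots=list(plots["plot_id"]))
pairs = build_pair_table(per_year[1], plots)     # 1,225 pairs of 50 plots
res = Dissimogram.from_pair_table(pairs, family="gompertz").fit()
print(res.summary())
```

```
Dissimogram fit
==============================================
family:        gompertz
n pairs:       1225
a (asymptote):  0.551671
b (shape):      0.170486
c (per m):     1.510e-04
nugget:         0.4652
pseudo R2:      0.0096
RSS:            17.206070
converged:     True   valid: True
```

The fitted asymptote 0.55 is the dissimilarity reached between distant
plots; the nugget 0.47 is the dissimilarity extrapolated to zero distance.
Their ratio (0.84 here) estimates the share of compositional variation due
to spatially unpredictable processes — consistent with the generating
ρ = 0.4 plus the binomial occupancy noise the generator adds on top. The
low pseudo-R² is typical of these data: distance explains little of the
pair-to-pair scatter even when the curve's intercept is well determined.

The same analysis on real data, with all strata and summary tables:

```bash
dissimogram run --surveys surveys.csv --plots plots.csv \
    --families gompertz,negexp --cutoffs 0.6,0.7,0.8 --out results/
```

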