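# Methods

## The estimator

Differences in species composition between two sites arise from spatially
autocorrelated environmental differences, from dispersal limitation, and
from chance. The effects of chance do not depend on how far apart the
sites are, so in the limit of zero geographic distance only chance
remains. The dissimogram makes that limit measurable: Jaccard
dissimilarity 1 − D′ for every unordered site pair is regressed on
pairwise Euclidean distance, and the fitted curve's intercept (the
nugget, by analogy with variography) estimates the chance component. The
asymptote estimates the dissimilarity between effectively independent
sites, so the nugget/asymptote ratio is a scale-free index of randomness.

Two curve families are fitted:

* Gompertz, D′(d) = a·e^(−b·e^(−c·d)): nugget a·e^(−b), asymptote a.
* Negative exponential, D′(d) = a − b·e^(−c·d): nugget a − b, asymptote a.
  (Several parameterisations of a saturating exponential exist; this one
  was chosen so that the (a, b, c)/nugget/asymptote bookkeeping is
  identical across families, and it is isolated behind the family
  abstraction.)

The approach assumes the dominant deterministic drivers are spatially
autocorrelated within the study extent, that the extent is large enough
for the dissimilarity to approach its asymptote, and that pairs at small
distances are numerous enough to pin down the intercept. It will mislead
when strong deterministic drivers are spatially patchy at lag zero (those
load on the nugget) or when dispersal limitation dominates at the largest
distances.

## Data aggregation rules

Point-count records (males displaying per plot × year × round × species)
are aggregated as: relative abundance = maximum count over the rounds of
a year; presence = recorded at least once in any round of the year;
cumulative composition = union of per-year presences. Aerial foragers
(swifts, swallows) can be excluded via a configurable species list — no
taxonomy is hard-coded. Pairs in which both communities are empty have
undefined Jaccard dissimilarity and are excluded with a logged count
rather than coerced to 0 or 1, which would bias the intercept.

Management-intensity strata split each region's plots at the regional
median of the supplied intensity score; plots exactly at the median go to
the low-intensity group so the split is deterministic (no published rule
exists for ties; any fixed choice is equally defensible and this one is
documented). Inter-annual turnover per plot is the transient fraction of
the cumulative species list, (n_cumulative − n_persistent)/n_cumulative,
where persistent species are those seen in ≥ 4 of 5 years (scaled to
⌈0.8·years⌉ when fewer years are supplied). Turnover cut-off strata drop
plots with turnover strictly above 60/70/80%; these strata are computed on
the cumulative composition, where the turnover filter is meaningful.

## Fitting

Parameters are estimated by Gauss–Newton least squares with
Levenberg-style damping: a pure Gauss–Newton step is tried first; if it
fails to reduce the residual sum of squares the normal equations are
re-solved with λ·diag(JᵀJ) added, λ escalating tenfold until the step is
accepted or damping saturates (which is itself taken as stationarity).
Convergence requires a relative RSS reduction or relative parameter step
below 1e-10 within 200 iterations. Distances are rescaled to kilometres
internally — c ≈ 1e-4 per metre is badly conditioned against a, b of
order 1 — and c is reported back per metre.

Multi-start initialisation: a₀ is the 95th percentile of observed
dissimilarity; b₀ ∈ {0.1, 0.5, 1, 2} (Gompertz) or a₀ − min(y) (negative
exponential); c₀ ∈ {1/median(d), 1/max(d), 10/max(d)}. The best converged
start wins (lowest RSS, then fewest iterations). No box constraints are
imposed during optimisation; instead a post-hoc validity rule flags fits
whose nugget falls outside [0, 1] (they indicate a poorly fitting model)
and the reporting layer carries them as "n/a". Constant-dissimilarity
input is handled as a degenerate flat curve (b = 0, nugget = asymptote =
the common value, flagged) because c is then unidentifiable; fewer than
three distinct distances is an error for the same reason. A few percent
of noisy single-year fits fail to converge within the iteration budget
(typically on a flat ridge where c → 0 makes a and b jointly
unidentifiable); these surface as "n/a" cells, which is the expected
behaviour of this estimator rather than an exceptional state.

Goodness of fit is the squared Pearson correlation between fitted and
observed dissimilarities (pseudo-R²); it is undefined and reported
missing when the fitted values are constant. Pseudo-R² values are
characteristically small for dissimogram fits — the intercept can be well
determined even when distance explains little pair-level scatter.

## Across-year summaries

Per-year nuggets (valid fits only) are summarised by their arithmetic
mean, sample standard deviation (n − 1 divisor), minimum and maximum;
missing years propagate and are never imputed. The 95% confidence
interval of the mean uses the t distribution with df = n − 1. A published
reference table of per-year nuggets for three German forest-bird regions
(bundled in `dissimogram.datasets`, since the underlying survey data are
registration-walled) pins the summary arithmetic in the test suite: every
printed mean/sd/min/max cell is reproduced to 4 decimals from the printed
yearly values. The same source's printed CI half-widths are *not*
consistent with t intervals at df = n − 1 computed from its own yearly
values (nor with any single df convention across regions), so they are
not used as assertions; this package reports the standard t interval.
Reported tables round nuggets to 4 decimals and CI bounds to 3.

## Occupancy and detectability

Per-species detectability uses the standard occupancy-detection
likelihood: for one plot with y detections in T occasions,
ψ·p^y·(1−p)^(T−y) when y ≥ 1 and ψ·(1−p)^T + (1−ψ) when y = 0. The
dynamic multi-season variant propagates the latent occupied/unoccupied
state between years with colonisation γ and extinction ε via a two-state
forward recursion, and reduces exactly to the static likelihood for one
season. Parameters are constant across plots and occasions (a single
overall ψ per species is the quantity of interest; covariate machinery is
out of scope). Missing occasions contribute no emission term
(missing-at-random). Estimation maximises the likelihood on the logit
scale (L-BFGS-B, finite-difference gradients, tolerance 1e-8) from a
{0.2, 0.5, 0.8} start grid; data with no detections give a boundary
estimate that is flagged, not raised. In field reports "detectability ψ"
sometimes glosses what is formally the occupancy parameter; both ψ̂ and p̂
are therefore reported, and the species-level summary averages ψ̂.

## The synthetic generator

The generator emulates the motivating study design — 3 regions × 50
plots, a 45 km square extent with ≥ 250 m plot spacing, ~80 species, 5
years × 5 survey rounds — while controlling the ground truth the nugget
is supposed to estimate. One environmental axis per region is a Gaussian
random field with exponential covariance exp(−d/range) (Cholesky
factorisation, 1e-10 diagonal jitter); the default correlation length is
9 km (a fifth of the extent), long enough that near-neighbour plots share
their environment. Species prevalences π_s are Beta-distributed with mean
0.57 (matching the mean detectability regime of the motivating surveys)
and sd 0.15. Each species' niche response is a steep logistic ridge
around a random optimum; its intercept is calibrated by bisection so the
across-plot mean response equals π_s. The calibration shifts the
threshold rather than rescaling the response, keeping responses near 0 or
1 — this matters, because the ρ = 0 limit is supposed to be
*deterministic given the environment*, and mid-range occupancy
probabilities would inject binomial noise that masquerades as randomness.
The niche steepness (12) was fixed once on that argument.

Occupancy probability mixes the two components convexly,
q = (1−ρ)·f_s(env) + ρ·π_s, so ρ = 0 is fully niche-structured and ρ = 1
fully random with q ∈ [0, 1] for all ρ. Yearly presences are independent
Bernoulli(q) draws (an optional persistence probability carries the
previous year's state forward, giving low-turnover regimes for testing
the turnover filter); per-round detections are Bernoulli(detection_p),
default 0.8 — with 5 rounds that is near-certain annual detection of a
present species, mirroring surveys described as fairly complete. Counts
are emitted as 0/1; the abundance pathway accepts arbitrary counts but
the generator does not model abundance structure.

What the generator does *not* emulate: temporal environmental change,
observer effects, multi-axis niches, dispersal limitation, species
interactions, or abundance dynamics. Passing recovery tests therefore
shows the estimator tracks the mixture weight ρ under idealised sampling,
not that field estimates are unbiased.

## Randomness-recovery study

For each ρ and replicate seed, a one-region community is generated,
per-year incidence matrices are built through the standard aggregation
path, a dissimogram is fitted per year, and the nugget/asymptote ratio of
valid fits is averaged. Per-year (not cumulative) composition is used
because the union of five independent yearly draws compresses
dissimilarities toward the detection ceiling and dilutes the mixture the
study is calibrating. With defaults (perfect detection, 20 seeds per ρ)
the mean ratio is ≈ 0.35 at ρ = 0, ≈ 0.81 at ρ = 0.5 and ≈ 0.94 at ρ = 1:
strictly increasing in the generating randomness, near 1 in the fully
random limit, and well below ½ in the structured limit. The ρ = 0 ratio
is not 0 — binomial presence noise and the intercept extrapolation leave
a floor — which is exactly the caveat a field estimate of the nugget
carries.

Problem sizes used by the bundled checks (chosen to characterise the
method at desk scale): 200-point noiseless and 1,225-point noisy pair
tables for parameter recovery; 300-point tables against a 50×50×50
grid-search oracle; 20 replicate communities per ρ; 150-plot × 5-occasion
detection histories for occupancy recovery.

## Numerical notes and limitations

* Exponent arguments are clipped at ±700 during optimisation so wild
  trial steps overflow to rejected candidates rather than NaNs.
* The Gauss–Newton damping accepts non-increasing steps; ties in the
  multi-start selection break by RSS then iteration count, making fits
  invariant to pair-table row order.
* Coordinates must already be projected (metres). Within regional extents
  of tens of kilometres, projection distortion of Euclidean distances is
  negligible; no geodesic path is provided.
* Jaccard here is the classic incidence-based index; estimator-adjusted
  (e.g. Chao) variants and abundance-based indices are extension points,
  not implemented.
* The nugget conflates true stochastic assembly with any unmeasured,
  spatially unstructured deterministic driver and with residual detection
  error; the turnover filters and detectability checks bound, but cannot
  eliminate, the latter.
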