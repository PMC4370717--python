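# Methods

This note documents the statistical procedures, the defaults and the
design choices of the `agribirds` package, in the order the pipeline
runs them.

## Species-level indices

**SSI** (habitat specialisation) is the coefficient of variation of a
species' density across the seven FBBS habitat classes (forest,
heath/scrub, marshland, farmland, urban, wetland/aquatic, rocks). The
standard deviation uses the sample (n−1) denominator by default — the
usual CV convention in the ecological literature — with the population
variant selectable (`sample_sd=False`); a species seen in a single class
therefore has SSI = √7 ≈ 2.646. Densities are mean birds per point
count per class; classes where the species was never recorded enter as
exact zeros, not missing values. **STI** weights the diet shares of
seeds/plants, invertebrates and vertebrates by 1, 2, 3; **SSIg** weights
abundance in unimproved grassland, improved grassland, mixed
grassland/arable and arable sub-habitats by 4, 3, 2, 1. Both are convex
combinations, so STI ∈ [1, 3] and SSIg ∈ [1, 4] by construction. The
packaged 22-species table is the authoritative trait source; the index
functions exist to document and extend it, not to regenerate it.

## Survey aggregation

Sites qualify with ≥5 farmland point counts; when more qualify, exactly
five are drawn uniformly with a caller-supplied seed, **once per site**
so the same points serve all years (comparability across years). A
point's farmland status comes from its first surveyed year. Per point ×
species × year the maximum of the two visit counts is taken (a missing
visit counts as zero, logged); the five maxima are summed per square and
averaged over the years actually surveyed, not over a fixed window.
Distance bands are accepted on input but summed — no detectability
correction is applied. Community descriptors use the 22-species
community only; other species are dropped with a warning. A site whose
community abundance is zero keeps richness 0 and carries NaN weighted
indices plus an `undefined` flag.

## Intensity and aggregation

IC/ha per SAR is the **ratio of sums** — total eligible input cost over
total eligible utilised area — per accounting year, then averaged over
the three years (2004–2006 by default). The ratio of sums weights farms
by area, matching the "total utilised area" definition and damping small
noisy farms; the mean-of-farm-ratios variant is selectable. Farms of
the excluded production types (vegetables, granivore livestock, wine,
orchards) are dropped before anything else. SAR eligibility requires
the five included production types to cover strictly more than
two-thirds of the SAR's agricultural area; the exact boundary is
excluded (implemented with a 1e-9 relative tolerance so floating-point
representation of 2/3 cannot flip it).

The aggregation index AI is the unit's intensity minus the mean of its
contiguous neighbours (binary rook/queen contiguity as supplied);
isolated units get an undefined AI. Classification uses |AI| <
mean(|AI|) → aggregated by default. The source convention for
"lower than the average value" is ambiguous (signed vs absolute, and
over which population), so `signed_mean` and `abs_median` rules are
selectable; all use strict inequality at the boundary.

## Spatial statistics

Moran's I uses binary, non-row-standardised weights throughout,
consistent with the explicit neighbour-count normalisation in AI.
Significance is a random-permutation test of value labels,
p = (1 + #{|I*| ≥ |I_obs|}) / (n_perm + 1), two-sided on |I| by default
(this randomisation procedure is what field software implements under
the looser name "bootstrap"). The correlogram builds one distance-class
weights matrix per (lo, hi] bin of centroid separation and reports the
class of maximal I; when every defined |I| is below 0.1 the correlogram
is flagged flat and the argmax is not meaningful. Residual spatial
checks average site-level model residuals within each SAR before
computing Moran's I between adjacent SARs.

## Covariates

CLC category areas become proportions of the site area (default 4 km²);
categories need not be exhaustive, so proportions may sum below 1.
Shannon diversity uses the natural log (base selectable) over the
renormalised present categories. The arable/grassland ratio is
a/(a+g) at SAR level. Climate is averaged over the survey years
(2006–2008 by default) on ingestion. Precipitation enters in mm by
default; an optional /1000 standardisation is provided because
coefficient magnitudes in national-scale analyses suggest such an
unstated rescaling, but the raw default is kept absent a documented
unit.

## Models

The "GAM" is an unpenalised **natural cubic regression spline with
fixed df** (default 2) inside an ordinary Gaussian least-squares model.
With df fixed there is no smoothing parameter to estimate, and AIC,
F-tests and leave-one-out identities are exact. The basis is the
classical truncated-power natural spline with df+1 knots at evenly
spaced quantiles of the regressor, columns centred; df = 1 collapses to
a linear term. The spanned space is affine-equivariant, so rescaling a
covariate never changes fitted values. Smooth blocks are tested by an
F-test of the whole basis block; single-column terms by t-tests. All
four descriptors, including richness, use a Gaussian identity link (a
count model is out of scope; richness at these sample sizes is far from
its bounds).

**Backward stepwise selection** drops, at each step, the single term
block whose removal lowers AIC most, until no removal lowers it.
Spline bases and interactions move as blocks; the focal intensity term
is protected by default, and main effects are never dropped while their
interaction remains. Greedy backward search is not guaranteed to match
exhaustive best-subset search, but on candidate sets of the size used
here it does (verified on random datasets); note that AIC-based
drop-one selection retains any pure-noise term with probability
≈ P(χ²₁ > 2) ≈ 0.16, so selected models legitimately keep some noise
terms.

**LOO-CV error** is mean |ŷ₍₋ᵢ₎ − yᵢ| / mean(y) × 100 by default, with a
per-observation-percentage variant. Predictions come from refitting on
n−1 rows with the design matrix fixed, which for these linear-in-
parameters models equals the hat-matrix identity e_i/(1−h_ii) exactly.

**The interaction model** codes aggregation 0 = non-aggregated
(baseline), 1 = aggregated; the factor's main effect is the intercept
difference and the product term the slope difference for aggregated
regions. Residual diagnostics report Shapiro–Wilk normality,
Breusch–Pagan homoscedasticity (against the model's own design) and the
SAR-level Moran permutation test; they never trigger automatic
refitting, and degenerate (numerically constant) residuals yield NaN
statistics rather than an error.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at the scale
of the national study: an 8 × 19 SAR lattice (152 regions) with rook
contiguity and 15 km centroid spacing, 332 sites with every SAR
guaranteed one site, and the packaged 22-species community.

* **Intensity field**: standard-normal noise smoothed by k iterations of
  x ← (x + neighbour mean)/2, k = round(10 × smoothing), rescaled to
  mean 405.1 and sd 150 €/ha (population sd, exact) and clipped at
  10 €/ha. Smoothing 0.8 (default) gives Moran's I ≈ 0.9 at this scale;
  0 gives white noise.
* **Farm records**: three eligible farms per SAR and accounting year
  with areas U(50, 150) ha; total cost is set so the yearly
  ratio-of-sums IC/ha reproduces the field exactly, split across farms
  proportionally to area and across the seven cost categories by a
  Dirichlet draw. A fraction of SARs (10%) also hold an
  excluded-production-type farm to exercise the filter.
* **Counts**: species s at site i has expected abundance
  λ = exp(a_s + f_s(X_i) + g_s·(X̄_nb − μ)), where f_s is
  β·exp(−X/250) for intensity losers (grassland specialists, SSIg ≥ 2;
  β = 1.5), β·(1 − exp(−X/250)) for winners (β = 1.0), or flat; the
  250 €/ha scale places the attenuation of the effect near the field
  mean, mirroring the observed flattening above ~400 €/ha. Baselines
  a_s are Gaussian across species (sd 1.2), giving common and rare
  species and realistic richness variation. The neighbourhood term uses
  the same neighbour-mean kernel as AI, so an intensity × aggregation
  interaction is directly plantable; the default g = −1.5e-3 per €/ha on
  grassland specialists mirrors the documented interaction on the
  community grassland index. Per point, N ~ Poisson(λ/5) (five points
  are summed downstream) and each visit records Binomial(N, p_det),
  p_det = 0.9; habitat classes are farmland with probability 0.8.
* **Covariates**: the site arable share is a logistic transform of a
  Gaussian with configurable correlation (default 0.6) to SAR
  intensity; pastures take the remaining farmland area and Dirichlet
  slivers of semi-natural categories part of the rest, deliberately
  leaving some site area outside the 15 tabulated categories (as real
  CLC tabulations do — and so the proportions are not collinear with
  the intercept). Climate and altitude are independent of intensity.

`generate_interaction_response` bypasses the count layer and builds a
site-level response y = b0 + b1·X + d0·A + d1·X·A + ε directly on a
generated landscape, with defaults at the magnitudes reported for the
national grassland-specialisation model (b1 = −1.165e-3 /€/ha,
d1 = +7.602e-4, noise sd 0.25); it backs the parameter-recovery and
calibration tests at exactly known truth.

### What the generator does and does not emulate

It reproduces the sampling design, the spatial autocorrelation of
intensity, winner/loser community turnover, detection thinning, and the
intensity–land-use correlation. It does not emulate observer
heterogeneity, overdispersed (beyond-Poisson) counts unless configured,
real SAR polygon geometry, or habitat-specific species densities within
a site. Passing tests therefore demonstrate the correctness and
calibration of the *method* under the assumed data-generating structure,
not conclusions about real bird communities.

### A misspecification caveat worth knowing

When the true intensity response is strongly nonlinear (the convex
decline of the loser species) and no interaction is planted, the
*linear* interaction model is misspecified: curvature leaks into the
X·A term because the aggregated and non-aggregated groups occupy
different parts of the intensity field, and the interaction t-test is
anticonservative. The calibration tests therefore plant no effects at
all on the null side; users testing interactions on real data should
pair the linear interaction model with the spline main-effect model, as
the pipeline does. Relatedly, the end-to-end power of detecting a
neighbourhood-mechanism interaction varies across landscape
realisations (the implied slope contrast is itself random); the power
property is verified on a moderately rough field (smoothing 0.3) with a
strong planted effect (g = −6e-3), where measured power is ≈0.9.

## Problem sizes and numerics

Simulation-based tests run at the study scale of 152 SARs × 332 sites
where the property demands it (parameter recovery: 200 replicates;
test calibration: 1000 replicates at model level; end-to-end power and
type-I: 10 full-pipeline replicates each) and at 20-SAR/30-site scale
for structural checks. Oracle-agreement tolerances are 1e-10;
closed-form identities 1e-12. Rank deficiency raises an error naming
the collinear columns rather than silently dropping terms; permutation
p-values respect the (1+k)/(1+n_perm) lower bound; all randomness flows
through explicit seeds and every pipeline output embeds the
configuration hash.

## Known limitations

* Gaussian identity link for richness (counts); adequate at these
  abundances, wrong for sparse communities.
* The aggregated/non-aggregated rule is one reading of an ambiguous
  convention; alternatives are provided but change group membership.
* Greedy backward AIC is exact only empirically, not provably.
* No currency deflation of input costs, no detectability correction,
  no GIS topology — adjacency and land-cover areas are consumed as
  pre-tabulated text.
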