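# Methods

## Overview

`ecostrategy` quantifies the "ecological strategy" diversity of land
mammals and birds from five species-level traits — body mass (g),
litter/clutch size, habitat breadth (count of suitable IUCN habitat
classes), generation length (years), and diet — and forecasts how that
diversity contracts under probabilistic 100-year extinction scenarios.
The package has four analytical layers:

1. **Trait preparation.** Diet is compositional (percentage use of ten
   categories at EltonTraits granularity), so it is first reduced to a
   continuous axis: Gower distances between diet compositions, then
   classical-scaling principal coordinates (PCoA), retaining axis 1 — a
   gradient from invertivores (positive, by sign convention) to
   herbivores.  The five analysis traits are transformed where it
   improves normality (log10 for mass, litter/clutch size and generation
   length; square root for habitat breadth; the diet axis as-is) and
   z-scored.  All surfaces and volumes live in these unitless "SD"
   coordinates.
2. **Strategy surface (2-D).** PCA of the five standardized traits;
   species scores on PC1/PC2 are averaged across the imputation ensemble
   after a deterministic sign anchoring (PC1: body mass loads positively;
   PC2: diet loads negatively).  Occurrence-probability contours are
   highest-density regions (HDRs) of a bivariate Gaussian KDE at the
   0.5/0.95/0.99 mass quantiles.
3. **Strategy space (5-D).** A one-class SVM (Gaussian kernel) fitted to
   the standardized points defines an in/out boundary; the enclosed
   volume (SD^5) is estimated by uniform Monte-Carlo sampling of an
   expanded bounding box.  Occupation of four null models of trait
   variation is tested by refitting the hypervolume to 999 (scaled: 99)
   null matrices per model and ranking the observed volume.
4. **Extinction forecasting.** Species are removed according to
   IUCN-category extinction probabilities over 100 years (CR 0.999, EN
   0.667, VU 0.1, NT 0.01, LC 0.0001); a randomized scenario removes the
   same number of species irrespective of traits.  Replicated scenarios
   give volume distributions compared by a two-sample KS test, percentile
   effect sizes against the observed volume, and rank-based permutation
   tests of back-transformed trait-summary shifts.

## Model and estimator details

### Gower / PCoA diet axis

Gower distance is the mean of per-variable range-normalized absolute
differences; variables with zero range carry no signal and are excluded
from the average (an input whose variables are all constant has
identical rows, and the distance matrix is identically zero).  PCoA is
classical scaling: eigendecomposition of the double-centered −½d²
matrix, scores scaled by the square roots of positive eigenvalues.
Gower matrices can produce negative eigenvalues; these are reported but
excluded from scores and from the variance-fraction denominator, and no
Cailliez/Lingoes correction is applied.  The diet axis-1 variance
fraction is therefore defined relative to the positive eigenvalue mass.
Species with wholly missing diet data receive a diet score through trait
imputation on the derived axis, not through composition imputation.

### Imputation

Chained-equation multiple imputation (MICE) with predictive mean
matching: each incomplete trait is regressed (OLS; ridge fallback with
penalty 1e-5 on singular designs) on the other four traits plus the
first ten phylogenetic eigenvectors — principal coordinates of the
tree's patristic distance matrix — and each missing cell is redrawn from
the observed value of one of the 5 donors with closest predictions.
Defaults: m = 25 chains, 10 sweeps, donors k = 5; the method's source
names no settings, so these standard chained-equation defaults are used
and exposed in the configuration.  Imputation operates on the
transformed (pre-z) scale; z-scoring is recomputed within each completed
dataset because z-parameters depend on imputed values.  Mammals and
birds are imputed separately (each class has its own tree and
eigenvectors) and concatenated.  Species absent from a tree fall back to
a trait-only regression rather than receiving eigenvector predictors.

### Hypervolumes

The one-class SVM is fitted with nu = 0.01 and a dimension-aware kernel
width gamma = 0.3 + 0.1·d (0.5 at d = 2), applied to internally
re-standardized coordinates.  Internal standardization makes the
estimator exactly scale-equivariant — dilating the data by c multiplies
the estimated volume by c^d — and the dimension-aware width counteracts
the outward smoothing bias of the soft boundary, which otherwise grows
with d: with a fixed width of 0.5 the unit hypercube in d = 5 is
overestimated by ~20%, outside the package's own accuracy gate for known
shapes (unit hypercubes and hyperspheres in d = 2, 3, 5 recovered within
20%).  The sampling box is the data range expanded by 20% per side;
volume = box volume × fraction of uniform samples classified 'in'
(default 500 samples per data point, capped at 5×10⁶).  Because the
boundary is refitted per species set, removing points can *increase* the
volume; no correction is applied, and scenario contrasts rely on the
paired randomized scenario rather than on monotonicity.

Set operations classify one common uniform sample over the union of the
two boxes with both boundaries, so the inclusion–exclusion identity
holds exactly at the label-count level.

### Null models and occupation

Model 1: independent uniforms over each trait's observed range.
Model 2: independent normals with observed means/sds.  Model 3:
independent permutations of the observed columns (marginals preserved
exactly).  Model 4: multivariate normal with the observed mean and
covariance (nearest-PSD repair if needed).  Null hypervolumes use the
same species count and SVM parameters as the observed fit so volumes are
commensurable.  Occupation is defined as V_obs / mean(V_null) — the
literal reading of "occupation of the mean of the null spaces"; the
mean-of-ratios alternative is also computed and reported.  The p-value
is one-tailed toward restriction: p = (1 + #{V_null ≤ V_obs}) / (n + 1).

### Extinction scenarios

Expected losses per category are round-half-away-from-zero of
count × probability; the default draw mode removes exactly that many
species per category (uniformly, without replacement), so projected and
randomized replicates always lose identical totals — the richness
control that makes volume distributions comparable.  Independent
Bernoulli draws are available as an option.  Data Deficient species are
treated as LC by default; alternatives drop them or assign the fixed
predicted probability 0.277.  Survivor volumes are measured in the
*global* z-context (the full observed set's transform and z-parameters
are never re-estimated after removals), keeping all volumes in the same
SD^5 units.  Trait summaries are back-transformed: geometric means for
log traits (an arithmetic gram-scale mean would be dominated by the
largest species), (mean √x)² for habitat breadth, and the arithmetic
mean of the z-scored axis for diet.  Trait-shift permutation tests are
rank-based and one-tailed in the direction of the observed-minus-mean
difference; because the direction is chosen from the data, the effective
two-sided size at nominal α is ~2α, which the calibration tests allow
for.  Effect sizes are observed volume minus per-replicate volume,
summarized as the mean with the 2.5/97.5 percentile interval (the CI
convention is the package's choice).

### KDE bandwidth

The HDR contours use a full (unconstrained) bandwidth matrix from the
normal-scale rule H = (4/(n(d+2)))^(2/(d+4)) · Σ̂.  An unconstrained
plug-in selector with a SAMSE pilot would track local structure better;
no installed library provides one and contour geometry — not any
headline statistic — is what depends on the choice, so the normal-scale
rule is the implemented selector.  The density grid (256×256 by
default) spans the data range padded by 3 bandwidth standard deviations;
the HDR level for quantile q is the smallest density whose super-level
set carries mass q.  On 10⁴ standard bivariate normal draws the
0.95-HDR area is recovered within 10% of the closed form π·(−2 ln 0.05)
≈ 18.82.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes,
with defaults fixed once as study conditions:

- 2000 species by default; class mix 33.8% mammal.
- log10 body mass: mammal mean 1.90, sd 1.00; bird mean 1.82, sd 0.60 —
  several orders of magnitude of mass, overall geometric mean ≈ 70 g.
- Gaussian copula on the transformed scale with the documented pairwise
  correlations (mass–generation length 0.41, generation length–
  litter/clutch −0.34, mass–diet −0.45, and the weak remainder), giving
  direct control of the correlations all downstream statistics consume.
- Diet: a latent gradient (the copula's fifth margin) interpolates
  between an invertivore and a herbivore Dirichlet profile (sigmoid
  steepness 5.0, concentration 25), sharp enough that the diet
  ordination separates the two guilds by sign with >95% accuracy at
  n = 500 — the signal the diet-axis machinery is required to find.
  Realized diet axis-1 variance fraction is ~0.44.
- Habitat breadth: 1 + Binomial(12, 0.19) through the copula's normal
  CDF — right-skewed integers, mean ≈ 3.3.
- IUCN frequencies: LC 0.708, NT 0.084, VU 0.081, EN 0.056, CR 0.025,
  DD 0.046.  Optional monotone mass–risk coupling ranks species by
  β·z(log mass) + noise and hands the severest categories to the
  largest-bodied species (β = 1.5 in the risk-coupled conditions), the
  structure the extinction-shift tests must detect.
- Missingness: litter/clutch 42%, habitat breadth 10%, diet 8% (whole
  rows), generation length 0.2%, body mass never missing; MCAR by
  default, MAR via a logistic in a driver trait with the intercept
  solved to preserve the marginal rate.

Not emulated: phylogenetic covariance of traits (the simulated pure-birth
trees are ultrametric and correctly structured, but traits are
exchangeable across them), taxonomy, and spatial pattern.  Passing tests
therefore demonstrate the machinery's correctness and calibration under
known structure, not the real-data values of loadings or volumes.

## Problem sizes and reproducibility

A single master seed drives named substreams (imputation chains,
hypervolume Monte-Carlo, null replicates, scenario replicates), so runs
are bit-reproducible and changing one stage's replicate count leaves the
others' draws unchanged.  The reference analysis used 999 replicates and
25 imputations at 15,484 species; the package's test and acceptance runs
use the scaled sizes 2000 species, 99 null replicates, 199 scenario
replicates and 5 imputations, which keep Monte-Carlo error small
relative to the effects being measured while remaining desk-scale.

## Known limitations

- SVM hypervolume values depend on (nu, gamma, sampling density); the
  published volumes for the real data are reproducible only under
  matching settings, which their source does not state.
- The normal-scale KDE bandwidth oversmooths multimodal surfaces
  relative to a plug-in selector; contour geometry shifts accordingly.
- PMM imputation cannot extrapolate outside the observed donor range.
- Occupation values are reported under both ratio conventions
  (V_obs/mean(V_null) and mean of per-replicate ratios); the two differ
  when null volumes are skewed.
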