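# Methods

`mycolight` implements an assemblage-level test of thermal melanism for
mushroom-forming fungi: whether the community-weighted mean (CWM) color
lightness of fungal assemblages increases with temperature, spatially and
seasonally, after accounting for confounders, sampling structure and shared
evolutionary history. This note records the models, the numerical choices,
and what the synthetic-data experiments do and do not demonstrate.

## Color trait

Species color is decomposed in the HSL cylinder. Each `#RRGGBB` sample maps
to hue H (degrees), saturation S and lightness L (both scaled 0–100); the
species trait is the arithmetic mean L over all samples (protocol: nine
points on a cross over each cap, at least one image per species). Hue is
angular, so species hue is the circular mean (atan2 of mean sine/cosine);
achromatic samples (S = 0) have undefined hue and are excluded from that
mean, and a zero resultant vector returns a missing value rather than an
arbitrary angle. Samples are pooled with equal weight across images —
per-image weighting would require knowing how many caps each image shows,
which the sampling protocol does not record. Hex encoding quantizes to
8 bits per channel, so decode–encode round trips are exact and lightness is
recovered to within 0.5 units.

A reliability check (`validate_against_reference`) regresses an independent
reference lightness (e.g. from standardized illustrations) on the
web-survey lightness by OLS and reports R², the slope with its confidence
interval, and a Wald test of slope = 1.

## Gridding, filters, CWM

Occurrences on planar (UTM-style) coordinates are binned into half-open
50 km × 50 km cells anchored at the CRS origin, `cell = (floor(x/s),
floor(y/s))` — deterministic and boundary-unambiguous. Records pool across
years into one binary cell × species matrix per month; duplicates collapse
to presence, because record counts in heterogeneous multi-source archives
reflect collector effort more than abundance.

Sampling-effort filters: cells with fewer than 25 species presences for a
nutritional mode are dropped *from that mode's analysis set* (each mode
keeps its own cell set); an optional whitelist restricts the species pool
to the mushroom-forming orders; for standardized local count data, species
recorded in fewer than 3 distinct months are removed. The 25-presence
threshold is read as "at least 25 distinct species present in the cell for
that mode", the most natural reading of a per-mode richness filter.
Filtering is idempotent.

CWM lightness is the unweighted mean trait over the species present
(presence weighting) or the count-weighted mean (abundance weighting, for
local fruit-body counts — linear count weights, the simplest reading of
"abundance-weighted"). Species without a trait are dropped with a warning
rather than imputed.

Environmental summaries per cell are means of finer-resolution subgrid
values, by default restricted to subgrids that actually hold fungal
records; an unweighted variant exists for robustness comparison.

## Climate reduction

Temperature and precipitation variable blocks are reduced separately by
PCA on the correlation matrix (bioclim-style blocks mix units, so
covariance PCA would be dominated by the largest-variance variable). Two
components are retained per block. Signs are fixed so each component
correlates non-negatively with the block's standardized row mean; the
component most correlated with that mean is labelled "overall means"
(thermal component 1 = mean temperature), the other "variability". A
collinearity screen flags predictor pairs with |r| ≥ 0.6; the retained set
is advisory — the screen informs, the caller decides.

## Null models and SES

Three randomizations of the binary matrix: `richness` permutes within
cells (row sums kept), `frequency` permutes within species (column sums
kept), `independent_swap` flips random 2×2 checkerboard submatrices
(both margins kept exactly; asserted on every draw). `n_swaps` counts
*successful* swaps (default 1000, with a 100× cap on proposals): counting
mere proposals would leave large matrices effectively unrandomized, and
the standard implementations of the independent swap count successes.

SES = (observed CWM − null mean) / null SD, with null moments over 100
independent randomizations seeded from a master seed. Draws that leave a
cell empty contribute no CWM and are excluded from that cell's moments;
cells with zero null SD get a missing SES. Nulls are run per mode and per
monthly matrix, mirroring the monthly response of the additive models.
Calibration: when the observed matrix is itself a draw from the null
ensemble, SES across ≥200 cells has mean ≈ 0 and SD ≈ 1 (checked for all
three nulls in the test suite).

## Trait–environment models

The additive model (GAM) of assemblage lightness uses Gaussian errors and:
cubic B-spline smooths with second-difference penalties for the four
climate components (sum-to-zero constraint absorbed by reparameterization);
a cyclic seasonal smooth over month built from Fourier sine/cosine pairs
with a frequency-squared ridge penalty (periodic by construction, so
December neighbours January); linear terms for UV index, forest cover and
log10 species richness; a low-rank thin-plate radial basis over (lon, lat)
with k-means knots; and a ridge-penalized per-grid random intercept.
Smoothing parameters minimize GCV over log-lambdas (Powell search from a
balanced initialization). Per-term significance uses a Wald-type
approximate F statistic on the penalized coefficients with the Bayesian
posterior covariance, rank taken as the rounded effective degrees of
freedom; adjusted R² uses the total effective degrees of freedom. These
are approximations in the penalized-likelihood tradition; exact equality
with any other GAM implementation's F values is not claimed.

One deliberate design choice: the *entire* spatial block is penalized,
including its linear plane. An unpenalized plane is exchangeable with any
latitude-driven climate gradient, and on gridded climate data this
concurvity silently reassigns the thermal effect to "space". Penalizing
the plane makes large-scale gradients load on the named climate
covariates, with the spatial term absorbing residual autocorrelation only.

The nutritional-mode contrast is a linear mixed model (lightness ~ mode,
random intercept per grid, REML), reporting the ectomycorrhizal effect
relative to saprotrophs with a large-sample Wald test. In balanced designs
the fixed effect equals the mean within-grid difference (tested to 1e-6).
Satterthwaite degrees of freedom are not provided; with hundreds of grids
the Wald approximation is adequate, and small-sample use should treat the
p-value as approximate.

The seasonal profile for local data is the cyclic month smooth alone; the
climate-change contrast is an OLS of Δlightness on Δtemperature over the
cells common to two climate intervals (e.g. 1970–1990 vs 1991–2010).

## Phylogenetic comparative methods

Signal indices on the species lightness trait: Pagel's λ by bounded ML
over the branch-length transform on [0, 1] (golden-section with boundary
snapping); Blomberg's K as the observed/expected MSE ratio under Brownian
motion with the GLS phylogenetic mean; Moran's I with inverse patristic
distances, zero diagonal, row-standardized; Abouheif's C_mean as the
Moran-type statistic on oriented proximities 1/∏dd(node) over the internal
nodes on each tip pair's path (MRCA included). p-values come from 99
tip-label randomizations, one-tailed toward clustering, with the standard
(1 + exceedances)/(n + 1) estimator, so p ≥ 1/100. The correlogram bins
patristic distances into equal-width classes (default 10), computes
Moran's I with binary row-standardized weights per class, and brackets
each class with a 95% percentile interval from tip resampling with
replacement; classes with fewer than two pairs are dropped (a two-tip tree
degenerates to the single global statistic).

Phylogenetic regression is GLS with the model-implied covariance: Brownian
(shared root-to-MRCA path lengths), Pagel λ (off-diagonal scaling, λ
profiled by ML) or stationary Ornstein–Uhlenbeck with random root
(covariance ∝ exp(−α d), α profiled on a log scale with boundary
warnings — α is weakly identified on star-like trees). Coefficient SEs use
the unbiased variance estimate; z tests are two-tailed; AIC counts the
regression coefficients, σ², and the profiled parameter. Identities held
to numerical precision: λ = 0 reduces to OLS; λ = 1 matches the Brownian
log-likelihood; the Brownian fit equals a direct solve against an
independently constructed covariance.

Species niche positions are unweighted means of cell environments over
occupied cells, dropping species on fewer than 10 cells (robustness of the
mean). Phylogenetic uncertainty is propagated by collapsing nodes with
support below 80 into polytomies and drawing independent random binary
resolutions (new edges of zero length; tip set unchanged).

## Synthetic worlds

The generator encodes the filtering hypothesis as a logistic occupancy
model: for each species × cell × month,

    logit P(present) = baseline + β · z(lightness) · z(temperature),

so β > 0 favors light species in warm cell-months — darker assemblages in
cold climates — and β = 0 is an exact null. β is the single recoverable
"filter strength"; its default 0.5 is a moderate effect chosen to give the
default-size experiment high but not saturated power, not an estimate of
any empirical effect size.

Components: a birth–death tree (pure birth by default) grown to the target
tip count, terminal edges extended by an Exp(n·birth) waiting time so all
branch lengths are positive, then rescaled to unit depth so trait rates
have a fixed scale; a lightness trait drawn from the multivariate normal
implied by BM / OU / λ (root 58, BM rate σ² = 80 per unit depth — chosen so
tip lightness has SD ≈ 9 and stays inside 0–100, matching a unimodal trait
centered near 58 on that scale; values clipped to [0, 100] with the clip
fraction reported, ≈ 0 at defaults); a symmetric two-state Markov walk for
nutritional mode (rate 0.3 per unit depth gives the phylogenetically
clustered mode pattern); a monthly climate field with temperature linear
in latitude (lapse 0.7 °C per degree over 20 degrees), a July-peaked cosine
season (amplitude 9 °C) and Gaussian noise, plus correlated precipitation,
UV and forest-cover fields; and nine hex color samples per species with
lightness noise SD 5, uniform hue, and mid-range saturation. All stages
draw their seeds deterministically from one master seed; identical config
and seed give byte-identical worlds.

What the generator does *not* emulate: spatially autocorrelated sampling
effort, taxonomic misidentification, range cohesion (occupancy is
independent across cells given the logit), observer-driven temporal
trends, and correlated hue/saturation structure. Passing the recovery
experiments therefore shows the estimators are correct and calibrated
under the stated model, not that every observational bias of real archives
is handled.

## Problem sizes and experiments

The default recovery experiment uses 150 species × 150 cells × 12 months
per world (the package's standard desk-scale configuration; the same
experiment at 300 × 300 behaves identically and is a one-line change).
At β = 0.5 the thermal-component-1 effect is detected (positive partial
slope, approximate F test p < 0.05) in essentially every seeded world;
at β = 0 the detection rate sits at the nominal 5%. SES calibration uses a
210-cell matrix with 100 randomizations × 1000 swaps; signal recovery uses
100 Brownian replicates on a 128-tip tree. `scripts/acceptance.py` reruns
all of these from scratch for any seed.

## Known limitations

- The GAM engine supports the model families this analysis needs, not the
  full generality of a dedicated GAM library (no tensor interactions, no
  non-Gaussian families, GCV only).
- Approximate F tests for penalized smooths are known to be slightly
  liberal or conservative depending on smoothing-parameter uncertainty;
  conclusions near p = 0.05 deserve a randomization check.
- OU regression assumes the stationary covariance (random root); fixed-root
  OU variants are not implemented.
- Tree dating and inference are out of scope: trees are consumed as given
  (Newick with optional support labels) and assumed correct.
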