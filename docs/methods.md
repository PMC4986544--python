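# Methods

This note records the models, defaults and design choices behind the
package, in the spirit of a statistical software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Response model

Tree density at a plot is a non-negative count (stems/ha, trees of
DBH ≥ 10 cm), modelled with a log-link NB2 regression:
E[y] = μ = exp(x'β), Var[y] = μ + μ²/θ, θ > 0 the dispersion. The NB choice
accommodates the strong overdispersion of inventory counts while keeping
zero densities (deserts, tundra margins) in-support; zero-density plots are
retained in fitting. Maximum likelihood is delegated to statsmodels
(`NegativeBinomial`, NB2 parameterisation); fits are polished with a Newton
step so ML identities (intercept-only fitted mean = sample mean) hold to
machine precision. Non-integer densities are rounded half-to-even with a
logged warning, since the NB likelihood requires integer support.

## Variable clustering

Covariate sets assembled for density modelling are heavily collinear.
Before selection, quantitative covariates are clustered by ascendant
hierarchical clustering of variables: the centre of a cluster is the first
principal component of its standardised members, homogeneity
H = Σ_j r²(x_j, centre) equals the top eigenvalue of the members'
correlation matrix, and each greedy step merges the pair minimising the loss
H(C_a) + H(C_b) − H(C_a ∪ C_b). Variables are standardised first (zero
mean, unit variance), which makes H(singleton) = 1, fixes the eigenvalue
identity, and renders the whole procedure invariant to affine rescaling.
The PC sign is anchored to correlate non-negatively with the
alphabetically-first member so loadings are deterministic; exact loading
ties resolve alphabetically.

**Choosing the cut.** No principled cluster count is implied by the data
volume alone, so the default cut is an elbow rule: with
d(k) = H(k) − H(k−1) the homogeneity cost of merging from k to k−1
clusters, the tree is cut at the k whose d(k) is largest relative to
d(k+1) — the level just before merge costs jump. Ties go to the larger k
(the more conservative cut). The cut is overridable per region. One
indicator per cluster (highest squared loading) enters model selection.

## Model selection and averaging

All 2^p subsets of the indicators (intercept always included) are fitted
and ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), where k counts the
regression coefficients plus one for θ — standard likelihood accounting.
Ties in AICc break on the lexicographic order of term-name tuples;
non-convergent subset fits are dropped from the ranking and logged, never
imputed. `p_max` (default 12) guards against accidental 2^20-fit requests.

Akaike weights over the ranking define the smallest prefix with cumulative
weight ≥ 0.95; weights are renormalised over that confidence set. Averaging
is *full* (zero-substitution): a term absent from a member model contributes
a zero coefficient, keeping averaged predictions shrinkage-consistent with
the weights. The averaged covariance is
Σ_i w_i [Cov_i + (β_i − β̄)(β_i − β̄)'] on the zero-padded union basis —
within-model uncertainty plus between-model spread — and θ̄ = Σ_i w_i θ_i.

**Regional rules.** A region needs ≥ 50 plots for its own model (the
threshold the bootstrap precision analysis supports: beyond ~50 plots the
s.d. of the predicted mean declines only marginally). Data-poor biomes
inherit a configured ecological analog; data-poor ecoregions inherit the
spatially coincident biome model. Ecoregions with enough plots to fit but
too few for stable clustering (fewer than 5 plots per candidate variable,
configurable) reuse the biome indicator set. All substitutions carry
`substituted-from:` provenance, propagated into the reliability flags of the
totals report.

## Spatial prediction

The scaling chain is strictly ordered and stage-checked:
raw trees/ha → truncation → per-pixel → forest-scaled.

- **Truncation at 10,000 trees/ha** is applied to per-hectare predictions
  before area and forest scaling. The ordering is interpretive (the
  operations are stated in this sequence in standard practice write-ups);
  it is enforced by the stage machine so a deviation cannot happen silently.
- **Pixel area**: square equal-area pixels, default side 897.27 m
  (0.805 km² = 80.509 ha); all grids are planar equal-area, so per-pixel
  area is constant. Geodetic area variation is out of scope.
- **Ratio scaling**: scaled = value · f_pixel / f̄, with f̄ the mean forest
  fraction at the *biome's* reference plots even when predicting with
  ecoregion models (switchable). Zero-forest pixels get exactly zero trees.
  f̄ and the forest-cover raster are treated as known constants — no
  auxiliary-data variance is propagated; a stated limitation.
- **Tiling**: prediction is per-pixel with no cross-pixel dependency, so a
  tiled run is bit-identical to an untiled pass and independent of tile
  order. That contract, not any particular parallel backend, is what the
  tests pin down. Totals accumulate in float64; rasters store float32 on
  disk.

## Uncertainty

For a regional total T = Σ_i s_i exp(x_i'β) with s_i = area_ha · f_i/f̄,
the delta method gives Var(T) ≈ g' Cov(β̄) g, g = Σ_i s_i μ_i x_i, using the
averaged model's combined covariance, so model-selection spread is included.
Pixels truncated at the cap are held fixed there — zero gradient in the
delta method and a hard min() inside the Monte-Carlo oracle — matching the
applied pipeline. The MC oracle draws β from N(β̄, Cov) (eigen square root,
tolerant of semidefinite covariances) and pushes every draw through the full
scaling chain; the two estimators agree within a few percent when
coefficient CVs are small, and the tests require 10% agreement at 20,000
draws. θ̄ enters estimation through Cov(β̄) but adds no extra
prediction-variance term: the target is the variance of the estimated total
of means, not a prediction interval for realised tree counts.

The global total is the exact sum of regional totals on the same surface.
The global variance groups regions by the model actually driving them:
substituted regions share their donor's coefficients, so their gradients are
perfectly correlated and their standard deviations add within a group;
across groups, fits are on disjoint data and variances add. Margins are
±2 s.d. throughout.

## Validation schemes

- **Stratified holdout** (default 20% per biome, `round(frac·n_b)` plots):
  models refit on the remainder predict the withheld plots; per-biome
  predicted means are regressed on observed means by OLS and the slope
  tested against 1 (two-sided t). At least 3 biome points are required;
  constant means raise a degenerate-regression error.
- **Bootstrap precision**: from a withheld pool, samples of size
  n = 10, 20, …, 500 are drawn with replacement; the curve records the
  standard deviation across replicates of the per-replicate mean prediction.
  An alternative reading — the mean of within-replicate standard
  deviations — is available behind `statistic="mean_within_sd"`, but only
  the default declines with n (σ/√n) and therefore supports a plateau
  analysis. Replicates default to 10,000; the test suite and CLI demos run
  1,000–2,000 to keep runtimes short, which only widens Monte-Carlo noise.
  The plateau rule reports the smallest grid n whose relative sd decrease to
  the next grid point falls below `rel_gain` (default 1%); a
  never-plateauing curve returns the largest n with a warning.

## Synthetic landscapes

The generator is first-class, tested code; its defaults define the study
conditions.

- **Covariates**: 20 bands (4 blocks × 5 variables) mixing a stack-wide
  latent, a block latent and a residual, all smoothed Gaussian noise
  (length-scale 5 pixels), giving within-block correlation 0.8 and
  between-block 0.05 — enough structure for the clustering stage to find
  and enough collinearity to make all-subsets selection non-trivial. Bands
  are standardised over the grid.
- **Regions**: nested Voronoi partitions (biomes, then ecoregions within
  biomes) of random seed pixels — contiguous, exhaustive, exactly nested.
- **Forest cover**: logit-normal surface f = expit(μ + σz), z a
  standardised latent mixing the first covariate band (weight 0.5, so ratio
  scaling has signal correlated with density) with fresh smooth noise;
  (μ, σ) solved by quadrature so the field's mean and s.d. hit 0.63 and
  0.35, the moderately-forested condition typical of inventory networks.
  Targets at or beyond the Bernoulli bound √(m(1−m)) are rejected as
  infeasible.
- **Plots**: pixel centres sampled with probability proportional to forest
  fraction (toggleable), reflecting where inventory plots actually sit.
  Note the size-biased consequence: the forest fraction *at plot sites*
  then averages above the field mean; `mean_reference_forest` measures
  whatever the plots actually see, so the ratio-scaling chain remains
  internally consistent. Counts are integer NB draws at the plot pixel's
  covariates.
- **Generative models**: per region, intercepts drawn for mean densities of
  100–500 trees/ha, two signal covariates with log-scale effects of 0.2–0.5
  and random sign, θ in 3–8. No published per-biome coefficients or
  dispersions exist to calibrate against, so these are realistic free
  choices, fixed once.
- **Problem sizes**: the end-to-end acceptance run uses a 100×100-pixel
  grid, 6 biomes × 2 ecoregions and 600 plots per biome; unit tests use
  smaller grids. These sizes make every stage's behaviour measurable while
  keeping the full suite fast.

**What passing does and does not show.** The synthetic fields are Gaussian,
stationary and exactly co-registered; plots have no location error,
no inventory-design heterogeneity (fixed vs variable radius), no
deliberately perturbed coordinates, and regions are Voronoi cells rather
than ecologically shaped. Recovery of generative truth here demonstrates
the pipeline's internal correctness — not that real-world totals would be
unbiased under covariate mismatch, plot-selection bias or
spatially-autocorrelated residuals, none of which are modelled.

## Numerical choices

- Half-open pixel footprints [x, x+Δ) × (y−Δ, y] make point-in-raster joins
  deterministic; a point on a shared edge belongs to exactly one pixel.
  Plot coordinates are interpreted in the stack's planar CRS; reprojection
  is an upstream, declared step, keeping joins bit-exact.
- Raster I/O uses ESRI ASCII grids plus a JSON sidecar for band names and
  the coordinate frame — plain-text, GIS-standard, and byte-reproducible.
- Covariance matrices are symmetrised after fitting; PSD is checked with a
  relative eigenvalue tolerance before any quadratic form; the MC sampler
  uses an eigen square root, so exactly-singular covariances are fine.
- AICc is undefined for n ≤ k+1 and raised as an error, not patched.
- Degenerate inputs fail loudly: constant variables in clustering, rank
  deficient designs, empty confidence sets, zero-sd log-log fits, empty
  bootstrap pools.

## Known limitations

- No spatial random effects or residual autocorrelation; plot observations
  are treated as independent within regions.
- Auxiliary forest-cover data is error-free by assumption; Var(f̄) is not
  propagated.
- The cluster count per region is an elbow heuristic, not a stability
  analysis; bootstrap-based k selection is out of scope.
- The truncation-before-scaling order is one reading of standard practice;
  the stage machine makes the choice explicit and auditable rather than
  configurable.
- Parallel execution is expressed as the tiling contract; actual
  multiprocess scheduling is left to callers.
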