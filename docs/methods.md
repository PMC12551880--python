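# Methods

## Data model

The unit of observation is the site-month: one crossing structure in
one calendar month. Photo records (site, camera, timestamp, species,
individual count, optional per-individual interaction codes, optional
period label) are chained into independent events per site × species
whenever consecutive photos are ≤ 30 minutes apart (a strictly larger
gap starts a new event; cameras are pooled within a site; species are
never merged). The 30-minute boundary is inclusive — a gap of exactly
30 minutes continues the event — matching the common camera-trap
convention; the threshold is a parameter (`gap_minutes`).

Interaction codes attach to individuals once per event (carried on the
first annotated photo; repeated annotation on later photos of the same
event denotes additional crossings). Classification caps A at two per
event (one crossing per direction; further back-and-forth is ignored)
and counts E once per event regardless of duration. Events lacking
codes — for example an active construction period during which
interactions were not assessed — contribute to the total-detections
matrix only, as do events whose period label is in the configured
exclusion list.

Rates are events per day: counts divided by days in the month, or by a
`days_monitored` column when a site was only partially monitored (the
default denominator is the calendar month; the override avoids rate
deflation in partial first/last months). Site-months with no
detections are retained as all-zero rows. Because multi-individual
events contribute each individual to its own category and bidirectional
crossings contribute two A's, the successful + failed rates can exceed
the total (event-count) rate in a cell; no inequality is enforced.

## Dissimilarity

Rate matrices are square-root transformed to damp hyper-abundant
species, then converted to zero-adjusted Bray–Curtis dissimilarities: a
dummy species with constant value d is appended to every sample, so

    BC(x, y) = Σ|xᵢ − yᵢ| / (Σ(xᵢ + yᵢ) + 2d).

Two empty site-months then have dissimilarity 0 instead of 0/0. The
default d = 0.03 is the smallest unit of a monthly rate matrix (one
detection in a 31-day month, 1/31 ≈ 0.032). The constant is applied on
the post-transform scale as a plain constant; note the mild
inconsistency that √(1/31) ≈ 0.18 ≠ 0.03 — the adjustment is a floor
for the denominator, not a rate, so it is taken at face value and is
configurable.

## Ordination and dbRDA

PCO is the eigendecomposition of the Gower-centred −D²/2. Axes with
positive eigenvalues carry scores scaled by √λ; negative eigenvalues
(Bray–Curtis is not fully Euclidean-embeddable) are reported but
excluded, with no Lingoes/Cailliez correction — total inertia is the
sum of positive eigenvalues. dbRDA regresses all positive-axis scores
on mean-centred predictors by OLS; R² is explained inertia over total
positive inertia and the adjustment is Ezekiel's
1 − (1−R²)(n−1)/(n−p−1). Significance uses row permutation of the
scores; partial tests use Freedman–Lane permutation of reduced-model
residuals. p-values follow the (exceedances + 1)/(n_perm + 1)
convention.

Rank-deficient designs: by default a singular design raises, naming the
dependent columns. Variation partitioning instead uses a rank-tolerant
mode in which aliased columns simply do not contribute (projection onto
the column space) and the Ezekiel penalty p is the design rank — the
convention of constrained-ordination software. This matters because
unions of site-level covariates and spatial eigenvector axes are
structurally rank-deficient whenever their count reaches the number of
sites, which realistic designs (18 sites, ~11 site-level covariates,
~10 selected spatial axes) do reach.

### Non-trivial axis criteria

Four criteria flag interpretable PCO axes:

* **broken stick** — observed % variation > bᵢ = (1/p) Σ_{k=i..p} 1/k;
* **bootstrap** — the lower 2.5% bound of the axis' bootstrap
  distribution (rows resampled with replacement, PCO recomputed) still
  exceeds the broken-stick expectation. The reference and quantile are
  configurable: published descriptions of this criterion vary and no
  machine-readable specification exists, so the conservative
  "pessimistic bound clears broken stick" form was chosen;
* **permutation** — observed % variation exceeds the (1−α) quantile
  under independent within-column permutations of the species matrix;
* **conditional** — as permutation, but % variation is computed as a
  share of the variation remaining after the previous axes.

## dbMEM bases

The truncation threshold t is the longest edge of the minimum spanning
tree of the pairwise distance graph (the smallest distance keeping the
neighbour graph connected). Distances > t are replaced by 4t (the
classical PCNM constant) and the truncated matrix is ordinated; axes
with positive eigenvalues are retained as orthonormal eigenvectors,
with Moran's I computed under the truncation-graph connectivity
weights. Eigenvalues agree with vegan's `pcnm` to ≈1e-10 (tested via
an Rscript oracle). For site-month designs the basis is computed on
unique locations (or months, counted from the first observed month) and
broadcast to observations — scores are properties of a location.
Separate bases are built per response design when sample sizes differ.

In the selection stage only axes with Moran's I above its null
expectation −1/(n−1) are candidates (positive autocorrelation, vegan's
`dbmem` default). This is not merely conventional: without it, AICc
forward selection on spatially structured communities can select enough
axes to span the entire between-site space, making every site-level
covariate exactly collinear with the spatial set. Negative-Moran axes
remain available in the basis object.

## Selection and screening

Forward selection minimises a distance-based AICc used for ranking
only: AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), with RSS the residual
inertia of the PCO scores after regressing on the current columns and
k = columns + 1. Selection stops when no candidate lowers AICc; ties
break by candidate order; base columns (the selected spatial and
temporal axes, when screening the measured sets) are always included.
VIF is 1/(1−R²) from auxiliary regressions with intercept; a VIF > 20
is treated as a flag, not a filter. Competing models (e.g. dropping one
of a collinear fencing/traffic pair) are compared by |PRESS − SSE|,
with PRESS computed per axis in closed form from leverages
h = 1/n + diag(Q Qᵀ); the model with the smaller gap is preferred.

## Variation partitioning

Adjusted R² is computed for all 31 non-empty unions of the five sets.
Intersection measures follow inclusion–exclusion over unions,
I(W) = Σ_{∅≠T⊆W} (−1)^{|T|+1} adjR²(T), and exclusive fractions by
Möbius inversion over supersets, f(S) = Σ_{W⊇S} (−1)^{|W|−|S|} I(W).
Both identities — Σf + residual = 1 and Σf = adjR²(all) — hold to
machine precision by construction, and the 2- and 3-set results equal
the textbook direct-subtraction formulas exactly (tested to 1e-12).
Negative fractions indicate interference between sets and are never
clipped. Per-set tests are partial dbRDA pseudo-F with Freedman–Lane
permutation, conditioning on all four other sets.

## Predictive model (MRPC)

Eigenvector bases are data-specific — adding a site changes the basis —
so the predictive model replaces them with raw UTM coordinates and a
month index. Retained PCO axes are regressed per-axis by OLS on the
mean-centred design; PCO scores are centred by construction, so
centring the predictors absorbs the intercept. Predictions for new
rows centre with the training means; values outside the training range
warn (extrapolated regression predictions are unreliable) but are
returned.

Drop-one-site cross-validation removes all months of one structure,
re-runs dissimilarity → PCO → OLS on the remainder (the drop model
retains the same number of axes as the full model so score spaces stay
comparable), predicts the dropped months, and computes five Mantel
correlations: M1 observed vs full-model fitted (all observations; a
full-model quantity, identical across folds); M2 observed vs fitted
within the training set; M3 observed vs predicted within the dropped
site; M4 full-model fitted vs predicted for the dropped site; M5
observed (all) vs the drop-model's fitted ∪ predicted configuration,
built entirely in drop-model space. Mantel r is invariant to rotation
and reflection of either score set, so no Procrustes alignment is
needed for M1–M5; an orthogonal-Procrustes helper exists for plotting
overlays only. M5's construction is one faithful reading of a
validation statistic whose published description is ambiguous.
Diagnostics: per-axis residual ACF (per site, ordered by month,
averaged, to lag min(10, ⌊months/2⌋)) and a Mantel correlogram over
Sturges geographic distance classes with Holm-adjusted p-values.
Assemblage profiles at predicted positions are inverse-distance-
weighted means of the k nearest training observations' transformed
species rates (exact match → that observation).

## Synthetic data

The generator emulates the monitoring design: sites with covariates
drawn at the published means/SDs (openness 0.338 ± 0.026, fencing
3371.5 ± 216.6, …), substrate water/concrete/dirt at 0.3/0.4/0.3,
catwalks at 0.4, UTM coordinates uniform in a ~60 km box, and monthly
precipitation/human/domestic/livestock covariates. Species log-rates
are linear in z-scored covariates through per-species loadings with one
effect-size multiplier per predictor set (default 0.3 on the log
scale), plus species-specific spatially and temporally autocorrelated
Gaussian fields (exponential covariance; ranges 10 km and 3 months)
and shared site/month random intercepts (SD 0.25). Counts are negative
binomial with Var = μ + θμ² (θ default 0.3; θ = 0 is Poisson). Monthly
counts expand into photo records whose events are separated by > 30
minutes while each event's 1–5 photos span < 30 minutes, so event
grouping recovers the generating counts exactly — a property tested
across seeds.

What the generator does not emulate: detection failure, species
interactions, diel activity patterns, camera malfunction, or any
nonlinear covariate response. Passing recovery tests therefore shows
the estimators work when the generating model is of the assumed form,
not that real crossing-structure data satisfy that form.

## Evaluation studies and problem sizes

Three simulation studies characterise the pipeline (module
`wcscomm.evaluation`; re-run by `scripts/acceptance.py`):

* **Type-I error** of the conditional set test: 200 replicates, 60
  observations, three null target and three null conditioning columns,
  199 permutations. The rejection rate at α = 0.05 sits near the
  nominal level.
* **Effect recovery**: 18 sites × 12 months × 20 species with the
  structural effect at 3× the other sets (0.9 vs 0.3); the full
  workflow (MEM selection, per-set screening, 5-set partition) must
  assign the largest focal unique fraction to the structural set.
* **Predictive validity**: 18 sites × 12 months × 15 species; the
  "signal" is defined as the covariate-predictable part of the rates
  (latent autocorrelated fields and random intercepts off), with
  additive Gaussian noise at 10% of each species' signal SD; six PCO
  axes are retained, covering the dominant structure of these
  low-noise communities. M3 ≥ 0.8 is expected for ≥ 90% of dropped
  sites.

These sizes mirror the emulated study design and keep the whole
evaluation under a minute on one CPU.

## Known limitations

* The AICc is a distance-based analogue; any monotone-equivalent
  variant yields the same selections, but absolute AICc values are not
  comparable across responses.
* Backward elimination steps in the set screening are not implemented
  (forward-only), matching the default workflow; the stepwise variant
  used in practice is not fully specified anywhere.
* The bootstrap axis criterion is one defensible operationalisation
  among several (see above).
* Negative PCO inertia is ignored rather than corrected; with
  zero-adjusted Bray–Curtis on sqrt-rates the negative part is small,
  but R² denominators would shift slightly under a Lingoes correction.
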