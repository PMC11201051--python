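# Methods

This note documents the models and procedures `nichemax` implements, the
choices made where the design was genuinely open, and what the synthetic
test battery does and does not demonstrate.

## The model

The core of the package is a maximum-entropy species distribution model.
Given presence points and a set of background cells drawn from the study
region, the fitted object is a Gibbs distribution over background cells

    q(x) = exp( Σ_j λ_j f_j(x) ) / Z,

where the f_j are features derived from the environmental variables and
Z normalises q over the background. The weights maximise the
L1-penalised training gain

    G(λ) = mean_presence[λ·f] − log Z + log N_bg − Σ_j β_j |λ_j|,

which is concave, equals 0 for the uniform model, and whose optimum
satisfies the KKT box condition |E_q[f_j] − mean_presence[f_j]| ≤ β_j,
with equality for features carrying non-zero weight. The per-feature
penalty is

    β_j = reg_multiplier · β_class(j) · sd_background(f_j) / √m,

with m the presence count and class levels 0.05 (linear, quadratic,
product), 0.5 (hinge) and 1.0 (threshold). These are fixed, documented
constants, configurable via `TrainConfig`.

### Features

Variables are rescaled to [0, 1] using background minima/maxima. The
default expansion is linear, quadratic, pairwise products, and forward
and reverse hinges; threshold features exist but are off by default
because hinges span the same expressiveness class with smaller models.
Hinge knots sit at equal background quantiles: with k knots per
direction (default 10), forward-hinge knots at quantile levels
0, 1/k, …, (k−1)/k and reverse at 1/k, …, 1, i.e. deciles by default,
excluding each direction's degenerate endpoint. A variable constant on
the background keeps only a (frozen) linear feature.

### Optimisation

Cyclic coordinate descent in feature-construction order, with an exact
1-D line search per coordinate: the coordinate derivative of the smooth
part, g(t) = mean_presence[f_j] − E_q[f_j], is strictly decreasing, so
the penalised coordinate optimum is 0 when |g(0)| ≤ β_j and otherwise
the unique root of g(t) = ±β_j, found by safeguarded Newton iterations.
Each accepted step increases the gain (the trace is non-decreasing by
construction), and the gain increment is credited to the stepped
feature's variable — product steps split 50/50 — which is what makes
percent contribution well defined. Coordinates already satisfying their
KKT condition at the sweep-start gradient are skipped. Convergence
requires both a relative gain change per sweep below `tolerance`
(default 1e-5) and a maximal KKT violation below the same tolerance;
hitting `max_iterations` (default 500 sweeps) instead returns the model
with a `converged=False` warning status, not an exception. With many
near-duplicate hinge features the tail of cyclic coordinate descent can
be slow, so small fits occasionally carry that status with gains within
about 1e-4 of the optimum; all downstream quantities are stable to this.

### Output scale

Raw densities q are converted to the logistic scale
p = e^H q / (1 + e^H q), where H is the entropy of the fitted
distribution over the background. This is a monotone transform
calibrated so a cell whose density matches the typical presence scores
about 0.5; the uniform (null) model scores exactly 0.5 everywhere.
Projection onto other climate layers clamps variable values to the
training range by default.

### Background

Background cells are a uniform, seeded sample of the stack mask (all
cells when the mask is at most `background_size`, default 10 000).
Presences are not added to the background; this is a documented,
configurable divergence risk relative to implementations that include
them.

## Variable screening

Stage 1 refits the model and removes every variable whose percent
contribution is numerically zero (below 1e-6 percentage points — the
printed-zero reading) until all survivors contribute. Stage 2 computes
pairwise Pearson correlations of the survivors *at presence points*,
visits pairs in decreasing |r|, and for each pair above the threshold
(default 0.8) whose members both survive, discards the lower-contribution
member; contribution ties discard the later variable in input order, and
a variable with zero variance at presence points is discarded as
degenerate. Pair order and tie-breaks are fixed purely for determinism;
correlation over background cells is available as an option.

## Evaluation

Occurrences are split 75/25 (test size = floor(0.25·n), remainder
trains), re-split per replicate deterministically from (seed, replicate
index); the default replicate count is 100. Model accuracy is the
presence-vs-background AUC, computed exactly via midranks (the
Mann–Whitney identity), with the shared background sample as the
pseudo-absence set. Grade bands are half-open: failure [0.1, 0.6), poor
[0.6, 0.7), average [0.7, 0.8), good [0.8, 0.9), excellent [0.9, 1.0],
values below 0.1 labelled "below scale". The suitability map used
downstream is the cell-wise arithmetic mean of the replicate logistic
maps; whether published maps of this kind are replicate means or single
runs is usually unstated, and the mean is fixed here.

## Habitat accounting and range dynamics

Suitability maps are cut at fixed thresholds into unsuitable [0, 0.1),
low [0.1, 0.3), medium [0.3, 0.5) and high [0.5, 1] habitat. Cell areas
use the spherical formula A = R²·Δλ·(sin φ_top − sin φ_bottom) with
R = 6371.0088 km (the single geodesy constant shared by thinning,
areas, and centroid distances); areas are reported in ×10⁴ km², rounded
to 2 decimals only in output files. The presence–absence matrix uses
the strict rule p > 0.5, so a cell at exactly 0.5 is "high" habitat in
the classification but absent from the binary range; this deliberate
one-cell discrepancy is tested. Range change between two binary maps is
the per-cell algebra (0,0) absent, (0,1) expansion, (1,1) retention,
(1,0) contraction, whose areas satisfy retention + contraction =
current area and retention + expansion = future area exactly; net
change = expansion − contraction. The range centroid is the
area-weighted mean of presence-cell centres (weighting by spherical
cell area is geometrically correct on lon/lat grids; the unweighted
mean is available), and migration between periods is the haversine
great-circle distance with the initial bearing in [0, 360).

## Occurrence handling

Ingestion accepts delimited text with longitude/latitude columns, drops
rows without parseable coordinates (counted), and collapses exact
duplicate coordinate pairs. Spatial thinning at radius 5 km is a greedy
first-come scan in input order: a point is kept iff it lies at least
the radius from every already-kept point ("within the radius" reads as
strict). Greedy retention is fixed for determinism; optimal thinning
(maximising the retained count) is deliberately not attempted.

## Synthetic data: what it emulates and what it does not

Because the original occurrence records and climate layers are not
redistributable, the pipeline is exercised on generated landscapes with
known ground truth:

- **Environmental layers** are standardised sums of ~10 random Gaussian
  bumps plus a latitudinal gradient on a 50×50 grid of 0.05° cells over
  lon [100, 102.5], lat [30, 32.5] (mid-latitude, so spherical area
  weighting matters). Layers are regenerated until mutually
  near-independent (|r| < 0.3).
- **The virtual species** responds through a logistic of a quadratic
  form in a few variables — unimodal per-variable responses with known
  optima — with the intercept calibrated to a prevalence of 0.05 and
  breadths of 0.4–0.8 layer s.d. These defaults describe a habitat
  specialist whose true presence-background AUC is about 0.95, the
  discrimination regime of a strongly climate-limited species.
- **The candidate set** for screening mirrors a 36-variable design:
  8 informative bases (the niche uses 4), 26 near-duplicate variants at
  target grid correlation 0.98 (restricted to presence points the
  sample correlation attenuates to roughly 0.85–0.95, still above the
  0.8 screen — as with real collinear bioclim siblings), and
  2 independent noise layers.
- **Scenarios** add exact offsets to chosen variables (default: +0.5
  layer s.d. on the first niche variable, a moderate warming analogue
  that keeps the shifted range on-grid for a specialist niche), so the
  direction the true suitability surface (and hence its centroid) moves
  is known analytically and can be compared with the fitted model's.
  Under larger shifts a projected range can legitimately vanish; the
  reporting layer treats an empty range as data (zero suitable area,
  centroid undefined) rather than an error.

What passing these tests shows: the implementation recovers a known
niche, screens redundancy correctly, discriminates strongly when the
species is strongly limited, and propagates range change and centroid
migration consistently. What it does not show: behaviour under real
spatial sampling bias, non-additive climate change, interactions the
quadratic form lacks, or WorldClim-like covariance structure among
variables — none of which the generator attempts to reproduce.

## Problem sizes used by tests and the acceptance script

Unit tests run on grids of 3×3 to 40×40 cells and fits with a few
hundred background cells. The recovery battery and the acceptance
script use the full 50×50 study landscape (2 500 background cells, all
of the mask), 894 or 500 occurrence draws, and 10 evaluation replicates
rather than the 100 a production run would use — the replicate mean is
already stable at 10 on these landscapes, and the numbers reported are
means over those replicates. The null-model check uses a 30×30 grid,
200 uniform presences and 20 replicates.

## Known limitations

- No bit-compatibility with the reference Java implementation of the
  maximum-entropy method: regularisation constants match its published
  conventions but optimisation paths, and hence percent contributions,
  differ numerically. Only structural properties (sums to 100,
  rankings on data with known ground truth) are asserted.
- No categorical features, sampling-bias grids, cloglog output, or
  spatially structured cross-validation.
- Reprojection and resampling are out of scope: all layers must share
  one lon/lat header, and areas are computed on the sphere rather than
  an equal-area projection.
- The ESRI ASCII grid is the only tested raster format.
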