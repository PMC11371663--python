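# Methods

`nichelegacy` quantifies how similar the realized climatic niches of two
related taxa are, and how much of the available climate space each
occupies.  The motivating design is a paired comparison: for each family,
one genus that went extinct in a focal region versus a congeneric-level
counterpart still extant there, both observed through their present-day
occurrences in a shared reference region.  A persistent niche difference
between the members of such a pair — in particular an extinct taxon
confined to warmer or more seasonal climates — is the signature one would
expect if past climate change drove the regional extinction.

## Niche space

The climate space is defined by a correlation-matrix PCA of the
bioclim-style variables over the *background*: every valid grid cell
inside the availability mask (e.g. the temperate-plus-tropical portion of
a continent), each weighted once.  Variables are centred and scaled to
unit variance over the background so temperatures (°C), precipitation
(mm) and unitless seasonality indices are commensurable.  Occurrences
are projected into this space afterwards — the "PCA-env" convention.
Whether the original analyses calibrated the PCA on background only or
on occurrences plus background is not decidable from their description;
background-only is the convention implemented, because it keeps the niche
space independent of which taxa are analysed.  Component signs are fixed
by flipping each axis so its largest-magnitude loading is positive; SVD
signs are otherwise platform-dependent.

## Occurrence handling

Records pass three accountable stages (input = retained + dropped at
every stage):

1. **Parse**: rows with unparseable or out-of-range coordinates are
   dropped and counted.
2. **Quality filter**: a record is kept only if its coordinate
   uncertainty is *strictly less* than half a grid-cell width (2250 m for
   a 2.5 arc-min grid; the default is computed from the cell size and can
   be overridden) and its record basis is an allowed value
   (`HUMAN_OBSERVATION`, `PRESERVED_SPECIMEN`, `LIVING_SPECIMEN`;
   fossil material is never climate-informative for a modern niche).
   Records with *no* uncertainty value are excluded by default — the
   strict reading of an "uncertainty less than" rule — with
   `keep_missing_uncertainty=True` as the permissive alternative.
3. **Downscaling**: each record maps to the grid cell containing its
   coordinate under a half-open convention (lon ∈ [west, east), lat ∈
   (south, north]), so edge points belong to exactly one cell; records on
   nodata or non-background cells are dropped and counted; multiple
   records in one cell collapse to a single occupied cell, so every cell
   carries equal weight downstream.

## Occupancy surfaces and Schoener's D

On an R×R grid (R = 100 by default, the resolution conventional for this
kind of analysis) spanning the background score range expanded by a 5%
margin per side, two kernel density estimates are evaluated at cell
centres and treated as discrete masses: the availability density *e* of
the background cells and the occurrence density *o* of a taxon's occupied
cells.  The corrected occupancy is

    r_i = o_i / e_i   if e_i ≥ floor · max(e),  else 0;      z = r / Σr

with floor = 1e−6.  Dividing by *e* converts "where the taxon is" into
"what the taxon prefers, given what was available"; the floor guards the
division at the climate-space fringe where *e* underflows.  The smoother
is a separable Gaussian-product kernel with per-axis Silverman reference
bandwidths (h_k = σ_k · n^(−1/6) for a bivariate sample) computed on the
sample being smoothed; the rule is parameter-free and standard, and
nothing in the source analyses pins down an alternative.  The same
surfaces and bandwidths are reused by the volume estimators, so "overlap"
and "volume" live in one space.

Overlap between two corrected occupancies is Schoener's D:

    D = 1 − ½ Σ_i |z1_i − z2_i|  ∈ [0, 1],

one minus the total-variation distance (0 = disjoint, 1 = identical).
Hellinger-based affinity (Warren's I) is available as a cross-check
metric only.

## Similarity and difference tests

The null question is directional: *is taxon A's niche more similar to
taxon B's observed niche than a niche placed at random in the available
climate space would be?*  Each pair is therefore tested twice (A
randomized against B observed, and vice versa).  Two null-generation
strategies are implemented:

* **shift** (default): relocate the randomized taxon's observed
  occupancy surface so its centroid sits on a support cell drawn
  uniformly at random (translate by whole cells, clip at the grid edge,
  zero outside the availability support, renormalize).  This preserves
  the observed niche *shape* and randomizes only its *placement*, which
  is the sharper reading of "a niche randomly generated from the
  available climate space".  A replicate shifted entirely off the
  support contributes D = 0 (it has no overlap to offer).
* **resample**: redraw the taxon's n occupied cells uniformly from the
  background and rebuild the occupancy surface with the same bandwidth
  rule.  This replaces shape and placement together.  Because this null
  is the same process that generates a taxon with *no* climate
  preference, the similarity-test p-value is exactly uniform under that
  scenario — the calibration property the acceptance suite checks.

With B replicates, p_similarity = (1 + #{D_null ≥ D_obs}) / (B + 1) and
p_difference = (1 + #{D_null ≤ D_obs}) / (B + 1): the add-one estimator
with ties counted as exceedances, so p ∈ [1/(B+1), 1] and never zero.
B = 1000 is the study default.  All directional p-values of one test
family across a study are adjusted together (Holm step-down by default;
Bonferroni and Benjamini–Hochberg are available — the original analyses
do not name their adjustment, so the default is documented rather than
asserted).  **B must satisfy m/(B+1) < α for m directional tests in the
family**, else no test can reach significance after adjustment; for the
13-pair design (m = 26, α = 0.05), B = 1000 gives a floor of 0.026.

A pair is classified per test: significant in both directions (‡), one
(†), or neither (–).  The "candidate climate legacy" pattern is a pair
that is neither similar nor different in any direction.

## Univariate overlap

Per climate variable, the overlapping coefficient between the two taxa's
values at occupied cells: fit a 1D Gaussian KDE to each sample (Silverman
bandwidth), evaluate both on a 1024-point grid spanning the union range
padded by 3× the larger bandwidth, and integrate the pointwise minimum
by the trapezoid rule (clipped to [0, 1]).  For two unit normals
separated by δ the true value is 2Φ(−δ/2), the analytic oracle used in
the tests.  Values are computed on cell values, not raw records, for
consistency with the equal-cell-weight policy; user-facing output is in
percent.

## Niche volume

Two estimators of how much of the available climate space a taxon
occupies, both in [0, 1]:

* **Schoener volume**: D between the taxon's z and the availability e
  renormalized over the support — 1 when occupancy mirrors availability.
* **HDR volume**: the 95% highest-density region (smallest set of grid
  cells whose summed KDE mass reaches 0.95, found by sorting cell masses
  descending; plateau ties are all included, avoiding threshold
  interpolation) is computed for the taxon and for the background on the
  shared grid; the volume is |taxon HDR ∩ background HDR| / |background HDR|.

Group comparison over pairs: medians per status group, a two-tailed
paired t-test on within-pair differences (all-zero differences are
degenerate and reported as p = 1 with a flag), and an OLS regression of
extinct on extant volumes (slope, r², slope p).

## Synthetic data

The generator emulates the *shape* of the real inputs with a known
ground truth.  Latent spatial factors — an east–west gradient, a
north–south gradient, optionally a smoothed random field — are
standardized over a lattice (default 60×60 cells of 0.05°); the 19
observed variables are fixed unit-norm linear mixtures of the latents
plus independent Gaussian noise (sd 0.1 in latent units), then given
arbitrary per-variable affine units.  Unit-norm mixing rows make the
noise-to-signal ratio uniform across variables and give the correlation
matrix exactly `latent_dim` dominant axes, mirroring the two-axis
structure of real bioclim PCAs.  The availability mask keeps the central
70% quantile band of factor 1 — excluding an "arid interior" without any
climate classification.  Species niches are Gaussians in latent-factor
space; records choose background cells with probability proportional to
the niche density at the cell's latent value, are jittered uniformly
within the cell, and carry log-normal coordinate uncertainties (median
500 m, log-sd 1) with 10% missing, so the filter's missing-value policy
is exercised.  Pair scenarios: `identical` (one niche, two record
seeds), `shifted` (centroids split along the full-range north–south
factor), `nested` (same centroid, breadths in a stated ratio).  Default
niche breadth is 0.5 latent SD and 500 records per species — a
moderately specialized taxon with a realistic post-filter sample
(~350 occupied cells).

What the generator does **not** emulate: real geographic structure,
real bioclim covariance (only its low-rank character), spatial sampling
bias, taxonomic error, or coordinate error correlated with habitat.
Green tests therefore demonstrate that the statistics behave correctly
under known niche structure — not that any particular empirical dataset
satisfies their assumptions.

## Numerical choices and degenerate inputs

* Occupancy requires ≥ 5 occupied cells; fewer yields a structured skip
  (in the pipeline) or an instructive error (at the library level).
* Zero-variance variables are dropped from the PCA with a warning; a
  background whose scores are degenerate on an axis is an error.
* Normalization is checked to 1e−6 on every Schoener's D input; the
  statistic itself is exact to round-off (oracle-checked at 1e−12).
* All randomness flows through explicitly passed seeded generators; the
  pipeline derives per-stage seeds as `sha256(master | pair | stage)`
  (< 2³¹), so any single pair can be reproduced without re-running the
  study.
* Rasters are plain-text ESRI ASCII grids; geometry mismatches between
  layers are a hard error, never a silent resample, and a cell missing
  any variable is excluded everywhere (no imputation).

## Problem sizes

The shipped analysis runs a 13-pair study on a 60×60-cell landscape
(2520 background cells, ~350 occupied cells per taxon, R = 100,
B = 1000) in a few seconds on one CPU; the test suite's calibration and
power experiments use B = 199 with 50–200 replicate runs.  These sizes
give the randomization tests their full resolution at the study's Holm
floor while keeping every experiment re-runnable interactively.

## Known limitations

* The niche space is two-dimensional by construction; taxa separated
  only along PC3+ are invisible to the overlap statistics.
* The shift null preserves bandwidths estimated from the observed
  sample; for very small n the null surfaces are smoother than a truly
  random taxon's would be.
* The KDE is not boundary-corrected: availability and occupancy both
  lose mass at the grid margin, which the shared 5% margin mitigates but
  does not remove.
* Schoener volume compares occupancy against availability *in shape*; a
  generalist with mild preference structure scores below 1 even if it
  occupies every cell.
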