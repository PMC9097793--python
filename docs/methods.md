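# Methods

## Overview

`genescape` implements a multi-species landscape-genetics analysis for
chloroplast (cpDNA) haplotype data: per-population diversity statistics,
spatially interpolated diversity and divergence surfaces, hotspot
delineation with protected-area overlap, isolation-by-distance tests, and
attribution of the diversity surface to climatic, topographic and
anthropogenic variables.  Because plastids are effectively haploid and
uniparentally inherited, each sampled individual carries exactly one
haplotype, and all genetic statistics operate on haplotype frequencies and
pairwise sequence distances.

## Population genetic statistics

**Haplotype diversity.** Nei's unbiased estimator
`H_D = n/(n-1) · (1 − Σ p_i²)`, with `p_i` the sample frequency of
haplotype *i* and `n` the number of sampled individuals.  `H_D = 0` iff the
sample is monomorphic; `H_D = 1` iff every individual carries a distinct
haplotype.  Undefined for `n < 2`.

**Nucleotide diversity.** `π = n/(n-1) · Σ_{i≠j} p_i p_j d_ij` with `d_ij`
the per-site proportion of differences between haplotypes *i* and *j*.
Sites where either sequence carries a gap or ambiguity (anything outside
A/C/G/T) are excluded pairwise, and each pair's `d_ij` divides by its own
number of comparable sites (pairwise deletion).  This estimator equals the
average per-site difference over all pairs of sampled individuals, which
the test suite verifies by exhaustive enumeration.

**Pairwise Φ_ST.** A two-population analysis of molecular variance on
squared inter-haplotype distances.  Squared distance between two
individuals is the number of nucleotide differences between their
haplotypes (pairwise deletion as above); a frequency-only option
(`distance="frequency"`, `δ² = 1` for distinct haplotypes) reduces Φ_ST to
the classical frequency-based F_ST.  Variance components follow the
standard sums-of-squares decomposition with the unequal-sample-size
coefficient `n_c = N − (n_A² + n_B²)/N`:

    Φ_ST = σ²_a / (σ²_a + σ²_w)

The estimator is unbiased, hence *negative* whenever the observed
among-population sum of squares falls below its null expectation —
including the exact-equal-composition case.  Negative values are stored
untruncated; truncation to zero is an option applied only when building
divergence surfaces.  Both populations monomorphic for the same haplotype
give zero total variance; that degenerate case is defined as Φ_ST = 0.
The matrix diagonal is 0 by definition.

Populations with fewer than five individuals are removed before analysis
(`min_n = 5`), the conventional cut for frequency-based statistics in
cpDNA meta-analyses.

## Landscape surfaces

Surfaces live on a regular geographic grid (WGS84 decimal degrees,
cell-center registered, row 0 northernmost — the layout of an ESRI ASCII
grid, which is also the raster interchange format).  The default
resolution is 2.5 arc-minutes (~5 km at the equator).  The grid covers the
study boundary's bounding box in whole cells; a cell participates when its
center falls inside the boundary polygon.

**Interpolation** is inverse-distance weighting with great-circle distances
(mean Earth radius 6371.0088 km) and power 2 (the common GIS default;
configurable).  All data points contribute — population counts are small
enough that no search radius is needed.  Exactly co-located data points are
averaged before interpolation so weights stay defined; a cell whose center
coincides with a data point takes that point's value.  IDW output is a
convex combination of the inputs, hence bounded by their range.

**Diversity surfaces** interpolate per-population `H_D`.  **Divergence
surfaces** use the midpoint construction: each population pair contributes
one synthetic point at the arithmetic lon/lat midpoint carrying the pair's
Φ_ST (negatives truncated by default).  Arithmetic midpoints are valid at
regional scale; regions crossing the antimeridian are not supported.  A
Delaunay-neighbor pair filter is available as an alternative to all pairs.

**Combination.** Per-species surfaces are clipped to the same boundary and
averaged cell-wise (raw averaging; min–max rescaling per species is not
applied).  Cell areas are spherical: `(res·π/180·R)²·cos(lat)`.

## Hotspots and protection

Hotspot cells satisfy `(v − mean)/sd > z` with `z = 1.5` by default; mean
and SD are population moments (divide by the cell count) over all
masked-in cells.  Flagged cells are grouped into connected components
(8-connectivity by default, 4-connectivity available) and labeled A, B, …
in descending order of spherical area.  A hotspot cell counts as protected
iff its center lies inside any protected-area polygon; the quantization
error of this rule is bounded by one ring of cells.  The outside fraction
is area-weighted: unprotected hotspot area over total hotspot area.

## Isolation by distance

Per species, the Mantel statistic is the Pearson correlation between the
upper triangles of the great-circle distance matrix (km) and the raw
(untruncated) Φ_ST matrix.  Significance is one-tailed ("greater", since
IBD predicts positive association) with `p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)`
under joint row/column permutations of the genetic matrix; 999
permutations by default, exact enumeration of all `n!` permutations for
`n ≤ 7`.  A planar lon/lat Euclidean geodistance is offered as an
alternative to great-circle distances.  An `F_ST/(1−F_ST)` linearization
of the genetic distances can be applied by the caller before testing.

## Environmental attribution

1. **Variable table.** Response = combined diversity surface sampled at
   its own masked-in cell centers; explanatory rasters on other grids are
   resampled nearest-neighbor.  Rows with any missing value are dropped
   and counted.
2. **Collinearity filter** (within category): while any pair has
   `|r| > 0.7`, take the worst pair and drop the member with the larger
   mean absolute correlation to the other remaining variables of its
   category (ties drop the lexicographically later name).  Deterministic
   and idempotent.
3. **Importance selection.** The two most important variables per category
   by random-forest permutation importance (500 trees, importance = mean
   drop in fit when a predictor is permuted, 10 repeats, seeded subsample
   of at most 10,000 cells).  Categories with exactly two variables pass
   through without fitting.
4. **GAMs.** Univariate penalized B-spline regressions (basis dimension
   10, cubic, automatic penalty-weight selection by the fitter's
   integrated criterion using a deterministic scalar optimizer — the
   stochastic basin-hopping default breaks bit-reproducibility).
   Adjusted R² uses the smooth's effective degrees of freedom.
5. **Variation partitioning.** With a univariate response, redundancy
   analysis reduces to ordinary least squares, so the partition is the
   standard varpart construction: OLS R² for the seven set unions (C, T,
   A, CT, CA, TA, CTA), Ezekiel adjustment
   `1 − (1−R²)(n−1)/(n−p−1)`, and inclusion–exclusion for the seven
   unique/shared fractions.  Fractions sum to `R²adj(CTA)` exactly (to
   1e−10); individual shared fractions may be slightly negative, a known
   artifact of adjusted R².

Spatial autocorrelation among grid cells is **not** corrected; p-values
and R² from cell-level regressions are descriptive, not inferential —
neighboring cells of an interpolated surface are not independent samples.

## Synthetic studies

The generator emulates the structure of a published multi-species cpDNA
meta-analysis over the Longitudinal Range Gorge Region of southwest China
(bounding box 95.79–106.12°E, 21.15–30.60°N), which is also the default
study-region fixture:

* 15 species by default, each with a pool of 12 aligned haplotypes of
  600 bp built by 1–8 random substitutions from a random root sequence,
  and 5–60 populations of 5–30 individuals at uniform random coordinates;
* per-population haplotype counts are multinomial draws from symmetric
  Dirichlet frequencies whose concentration rises geometrically (0.06 →
  1.5 per haplotype) along a configurable gradient direction (northward by
  default).  Expected heterozygosity under this scheme is
  `α(K−1)/(1+Kα)`, recorded per population as ground truth, so expected
  `H_D` rises along the gradient — the planted signal recovery tests look
  for.  Roughly half the populations come out monomorphic at the default
  concentration range, matching the character of real cpDNA samples;
* a "contaminated" mode plants populations with `N < 5` to exercise the
  sample-size filter, with the true count recorded;
* environmental rasters: topographic = the two coordinate fields plus two
  smooth Gaussian random fields; climatic = affine functions of latitude
  plus smooth noise (inducing a known climate–topography overlap),
  including one pair planted collinear at r ≈ 0.9 to exercise the
  collinearity filter; anthropogenic = two independent smooth fields;
* protected areas cover an exactly known fraction of target cells (whole
  cell rectangles accumulated until the requested area share is reached),
  so the expected outside fraction is known to one cell's quantization.

What the generator does *not* emulate: migration, range limits and
spatially clustered sampling, coalescent genealogies, realistic climate
fields, or localized diversity peaks.  In particular, a smooth directional
gradient produces a combined surface with a broad plateau rather than
isolated peaks, so the default study typically contains **no** cells more
than 1.5 SD above the mean — hotspot behavior is therefore tested on
constructed plateau surfaces with known components, and passing tests
demonstrate correctness of the machinery, not that any particular real
landscape has hotspots.

## Pipeline, determinism and problem sizes

`run_pipeline` executes read → filter → statistics → per-species surfaces
→ combination → hotspots → protected overlap → IBD → variable extraction →
collinearity filter → importance selection → GAMs → variation
partitioning, writing every intermediate artifact (CSV, ESRI ASCII,
GeoJSON, JSON) plus a manifest with package version, parameters and seed.
All randomness (simulation, Mantel permutations, forest fitting, subsample
draws) derives from one master seed through spawned generators; identical
configs give bit-identical outputs.  The pipeline is a deterministic
single pass — stage caching was considered and rejected as needless state
for runs that complete in minutes.  Fitting stages run on seeded
subsamples by default (4,000 cells for the random forest, 2,000 for GAMs)
— interpolated surfaces are heavily oversampled at full grid resolution,
so subsampling changes estimates negligibly while keeping the end-to-end
run at the 2.5-arc-minute study scale (~56,000 grid cells, 15 species)
around three minutes on one CPU.

## Numerical choices

* Distances below 1 mm (1e−9 km) count as coincident in IDW.
* Grid extents get a 1e−9° slack before ceiling so exact-multiple
  bounding boxes do not gain a spurious row/column.
* Zero-SD surfaces yield an empty hotspot list (detection) but an error
  where a threshold value is explicitly requested.
* Collinearity-filter ties break lexicographically; importance ties break
  by variable name after sorting on importance.
* OLS designs are rank-checked before solving; rank deficiency raises an
  error naming the offending columns.

## Known limitations

* Regional-scale assumptions: arithmetic midpoints and degree-based grids;
  not suitable across the antimeridian or for global extents.
* Cell-center containment for masks and protection status quantizes areas
  by up to one cell ring.
* The AMOVA is strictly two-level (within/among two populations); no
  hierarchical groupings, neutrality tests, or haplotype networks.
* Attribution treats grid cells as exchangeable observations; see the
  autocorrelation caveat above.
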