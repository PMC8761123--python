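# Methods

## Raster model and I/O

A raster is a 2-D float array with an explicit boolean nodata mask and an
affine geotransform `(origin_x, origin_y, pixel_width, pixel_height)`;
row 0 is the northern edge, so `pixel_height` is negative for north-up
grids and the centre of cell `(r, c)` sits at
`(origin_x + (c+0.5)·pixel_width, origin_y + (r+0.5)·pixel_height)`.
GeoTIFF read/write is implemented over `tifffile` with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA,
GeoAsciiParams); only single-band files are handled and the CRS is
carried as an opaque label — there is deliberately no reprojection
engine. Resampling onto a template grid supports `nearest` (takes the
validity of the sampled source cell; intended for categorical layers) and
`bilinear` (any contributing nodata cell poisons the output cell; intended
for continuous variables). A pixel enters the analysis table only if it is
valid in **every** layer, so removing a layer can only grow the table.

## Collinearity pruning

`VIF_j = 1/(1 − R²_j)` with `R²_j` from the least-squares regression of
variable *j* on all others plus an intercept, computed on z-scored columns
for conditioning; the result is invariant to affine rescaling of any
column. Exactly collinear variables are flagged with a sentinel of 1e12
rather than raising, and always outrank finite VIFs in the removal
choice. The pruning loop removes the single worst variable per iteration
until all survivors fall below the threshold (default 5); ties at the
maximum remove the variable later in the input order, making the trace
deterministic. Tables longer than 200 000 rows are scored on a seeded
uniform row subsample — VIFs are O(n·p²) and already stable at that size.

## Clustering

Variables are z-scored before clustering: mixing °C, mm, %, W/m² and
mg/m² in one Euclidean distance is meaningless otherwise. Lloyd
iterations use scikit-learn's `KMeans` (k-means++ seeding, `n_init = 10`,
empty clusters re-seeded internally); labels are reported 1..K. The
hill-climbing refinement then sweeps single observations, moving x from
cluster s to t whenever the size-corrected change
`Δ = n_t/(n_t+1)·d²(x,c_t) − n_s/(n_s−1)·d²(x,c_s)` is strictly negative,
updating centroids incrementally and stopping when a full sweep finds no
improving move; moves out of singleton clusters are forbidden, and the
final SSE is recomputed from scratch so the reported value never exceeds
the Lloyd SSE. This escapes Lloyd fixed points that a single reassignment
can improve (the classic wide-rectangle configuration is the regression
test).

K is chosen by the average silhouette width
`s(i) = (b_i − a_i)/max(a_i, b_i)` (Euclidean), with two conventions:
singleton clusters and coincident clusters (a = b = 0) both score 0. The
profile over a K range reports the global argmax and strict local peaks.
Because full silhouette is O(n²), each K is evaluated on a seeded
subsample (default 10 000 pixels) of a full-table fit.

The majority filter replaces each labelled cell by the modal label of its
3×3 window (one pass by default); nodata cells never vote and never
change, and ties retain the original label so boundaries do not erode. A
cluster consisting entirely of speckle can vanish; surviving labels are
then compacted to 1..K′. Subclusters are connected components
(8-connectivity by default) lettered by descending pixel count;
components below `min_area_pixels` (default 25) are pooled into a single
unlettered remainder per cluster — tiny islands are noise at reporting
scale.

## Cluster profiles

The shared value of a variable in a cluster is
`100 · (max − min within cluster)/(max − min over all valid pixels)`,
undefined (NaN, excluded from rankings) when the region-wide range is
zero; the min/max range is used rather than a trimmed range. Areas use
the spherical formula
`(R·Δlat)·(R·Δlon·cos(lat_center))`, R = 6371.0088 km, per pixel row for
geographic grids, and `pixel_width·|pixel_height|` (km assumed) for
projected grids; cluster areas sum to the total valid area by
construction. The environmental dendrogram is complete-linkage (Euclidean)
agglomeration of the per-cluster variable means z-scored **across
clusters**; z-scoring was preferred over range-normalization because the
latter is unstable with ~10 rows. Variables constant across clusters are
dropped with a warning. Dendrograms are compared by the Pearson
correlation of their cophenetic distance matrices over shared leaves, and
exported as ultrametric Newick strings.

## Endemism analysis

Checklists are tables with `taxon, family, genus, rank` plus `unit:<id>`
0/1 columns (CSV or XLSX); duplicate names collapse to the union of their
flags with a warning. The occurrence matrix is units × taxa binary; taxa
present nowhere are dropped, and units hosting no endemic taxon are
excluded by default (a flag keeps them), mirroring the standard treatment
of endemic-free desert units.

IndVal follows Dufrêne–Legendre: for taxon i and class j,
`A_ij = mean presence in j / Σ_k mean presence in k` (specificity, sums
to 1 over classes), `B_ij = fraction of units of j where present`
(fidelity), `IndVal_ij = 100·A_ij·B_ij`; the observed statistic is the
maximum over classes and the null permutes the unit→class assignment.
The Monte-Carlo p-value uses the add-one form
`(1 + #{null ≥ observed})/(1 + n_perm)` so p is never 0; an exact mode
enumerates all distinct label arrangements (identity included) for small
designs and is verified against a brute-force oracle. The degenerate
design in which every cluster is its own single-unit class is supported
but statistically weak — with 11 units the smallest achievable p is 1/11,
so few taxa can ever reach p < 0.05 there.

Two statistical properties of binary IndVal worth knowing:

- With **equal class sizes** the max-IndVal statistic collapses to a
  function of integer per-class counts, so its permutation distribution
  has few large atoms and p-values are strongly super-uniform (the test
  rejects far below nominal level). With unequal class sizes the
  statistic is effectively continuous and the test calibrates almost
  exactly. The calibration study therefore uses 5 classes of 2, 3, 5, 7
  and 11 units (28 units), occupancy 0.3 everywhere, 2000 taxa and 1000
  permutations, and observes rejection at p < 0.05 within 0.046–0.055
  across seeds.
- Sensitivity to planted class-level indicators (p_home = 0.95,
  p_background = 0.02) grows quickly with units per class: it straddles
  80% at exactly 3 units/class and reaches 93–97% at 4 units/class. The
  sensitivity study uses 6 classes × 4 units.

The species–area relationship `E = c·A^z` is fitted by ordinary least
squares of ln E on ln A over units with positive area and endemic count
(at least 3 required). The endemism-density index is defined as observed
over area-expected richness, `α = E/(c·A^z)`; by the OLS residual
property the geometric mean of α over fitted units is exactly 1, which
the tests check to 1e-9. Units with zero endemics are excluded from the
fit but listed with α undefined. The linear-scale area–richness R² is
reported separately (it is the quantity that is near zero when large
desert-like units carry few taxa).

## Synthetic data

The landscape generator plants `K_true` contiguous regimes as Voronoi
cells of seed points placed by best-candidate (farthest-point) sampling,
which keeps cells comparably sized so every planted regime is
substantively present for any seed; a smoothed-random-field geometry is
available for non-convex regions. Regime mean vectors default to binary
contrast patterns (greedy max–min Hamming selection over random
candidates) scaled to `separation_sd × within_sd` (default 3 × 1), so any
two regimes differ by the stated separation in several variables at once.
Each base variable is its regime mean plus spatially smoothed Gaussian
noise rescaled to the within-regime sd; collinear blocks append derived
variables (linear combination of base variables plus noise at a stated
fraction of the combination's spread, default 5%) to exercise the VIF
loop; a nodata border (default 5% of the short side) exercises masking.
The flora generator gives each taxon a home unit (or, given a unit→class
map, a home class) and draws presences as independent Bernoulli flags —
`p_home` at home, `p_background` elsewhere — with family labels sampled
from a weighted pool shaped like a Mediterranean endemic flora. All
randomness descends from one root seed through named CRC-keyed
substreams, so any stage regenerates independently.

What the generator does **not** emulate: realistic climate fields and
their cross-correlations, gradients within regimes, spatially
autocorrelated sampling effort, taxonomic errors, or range shapes beyond
unit membership. Passing recovery tests therefore demonstrates the
machinery is correct under known structure, not that real Maghreb-scale
rasters would yield any particular K or variable set.

## Problem sizes and defaults

The test and acceptance studies run on the tiny fixture (60×60 grid ≈
2 900 valid pixels, 6 base + 2 collinear variables, K_true = 5,
silhouette subsample 1 500) and on flora designs of 400–2 000 taxa with
1 000 permutations; the `standard` fixture (200×200, 33 variables,
K_true = 11) mirrors a full-scale variable count for heavier local runs.
These sizes were chosen so the whole suite completes in seconds while
leaving every statistic far from its small-sample breakdown.

## Known limitations

- No reprojection: all layers must already share a CRS; resampling only
  aligns grids within it.
- The silhouette subsample makes the K choice stochastic for marginal
  profiles; fix the seed for reproducibility.
- The hill-climbing pass is O(sweeps × n × K) in Python loops — fine at
  10⁴–10⁵ pixels, slow at millions; run k-means alone first if needed.
- The α-index formula (observed/expected from the fitted power law) is
  one of several definitions in use; an exponent-ratio variant is not
  currently implemented.
- Binary IndVal inherits the discreteness caveats above; interpret
  p-values under few-unit designs accordingly.
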