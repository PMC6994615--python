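# Methods

This note documents the models, parameter choices and numerical
conventions behind `lidarstands`, and what the synthetic test bed does
and does not establish about real data.

## Rasterization

Point clouds arrive classified (ground / vegetation); no noise
filtering is performed here. The DEM is the per-cell minimum ground
elevation on the analysis grid, with empty cells filled by iterative
8-neighbor averaging; heights above ground are obtained by bilinear
interpolation of the cell-center DEM, with residuals in [−0.5, 0) m
clamped to zero (sensor noise below the ground surface).

Grid convention: row 0 at map north, origin at the outer corner of
pixel (0, 0), half-open pixel intervals — a point on a shared edge
belongs to the pixel with the larger row/col index. Nodata is the
−9999 sentinel and is masked from every statistic.

The three segmentation bands live on a 4 m grid:

- **height**: nearest-rank 85th percentile of all return heights per
  pixel (`k = ceil(p/100·n)` on the sorted sample). Nearest-rank rather
  than interpolated percentiles keeps integer-hit semantics and makes
  brute-force oracles exact. Percentile 100 equals the per-pixel
  maximum.
- **density**: fraction of returns above a 1 m vegetation cutoff. An
  alternative reading — returns above the pixel's own height
  percentile — is implemented behind `mode="percentile"` but is not the
  default, because a fixed 1 m break matches the below-1 m conventions
  used by the plot features.
- **classification**: per-pixel Gaussian maximum likelihood over the
  3 image bands with equal priors and per-class diagonal covariance;
  ties go to the lowest class index in the fixed order (bare,
  low_vegetation, forest). Accuracy is summarized by Cohen's kappa.

Both continuous bands are median-filtered (3×3, nodata-aware, windows
clipped at edges) and mean-shift-filtered (spatial radius 2 px,
spectral radius 0.1 for density and 2 m for height, ≤20 iterations to a
1e-3 fixpoint). The mean shift averages only neighbors within the
spectral radius, so plateaus separated by more than it are never mixed
— this is what keeps stand borders sharp while removing pixel noise.

## Stand segmentation

The composite enters the gradient and the growth dissimilarity in
min-max-normalized units; merging operates in raw units (density
fraction, height in metres). The classification band is categorical
throughout: the difference between two classes is 0 if equal and 1
otherwise, and a region's class statistic is its modal class with the
modal fraction as spread.

**Gradient.** Per band, central differences (one-sided at edges),
magnitude `sqrt(gx²+gy²)`, weighted sum over bands, rescaled to [0, 1]
by its maximum. Rescaling makes the seed schedule scale-free and the
gradient invariant to a common weight factor.

**Seeds.** At each level `L` of the priority function, unassigned
pixels that are 3×3 local minima of the gradient with value ≤ `L`; of
each 4-connected equal-valued plateau only the row-major-first pixel is
kept. Levels ascend, so seed finding relaxes over iterations and new
seeds appear only where nothing has grown yet.

**Growth.** Best-first competition over 4-neighbors with a priority
queue keyed by the weighted L1 dissimilarity between pixel and region
mean (L2 available). A pixel is annexed only while the dissimilarity is
at or below `competition_threshold × (level index + 1)`; the scale
factor is the package's reading of the undocumented interaction
between the priority function and the competition threshold, and a
constant-bound variant is switchable. Ties resolve by smaller
dissimilarity, then smaller segment id, then row-major order, making
the whole stage deterministic. After the last level, remaining pixels
are attached to the least dissimilar adjacent region with no bound, so
the result is a full partition.

**Merging.** Four rounds of threshold merging with per-band mean and
standard-deviation ceilings that relax round by round; each round is
swept (ascending segment id, statistics updated after every accepted
merge) until no merge occurs. A segment merges with its most optimal
neighbor — the argmin of the band-weighted sum of mean and std
differences — and may equally merge with a neighbor for which it is
itself the optimum. A merge is admissible when every band passes both
ceilings and the combined area stays within the 5 ha maximum.

The standard-deviation difference is read as the **heterogeneity
increase** the merge would cause, `std(A∪B) − max(std_A, std_B)`
(floored at 0), not as `|std_A − std_B|`. Under the pairwise reading
the published density ceilings (0.0 → 0.02 across rounds) block nearly
every absorption of a small segment by a large one, because sample
standard deviations of small segments are biased low by spatial noise
correlation alone; under the variance-increase reading every published
value is functional (round 1's 0.0 means "no heterogeneity growth")
and cross-stand merges stay blocked because the mean gap inflates the
merged variance. The pairwise reading remains available as
`MergeParams(std_mode="pairwise")`.

Finally every segment below the 500 m² minimum mapping unit is
absorbed into its most optimal neighbor (ceilings waived), smallest
first; labels are compacted to 1..K and polygonized as unions of pixel
squares (4-connectivity).

Expected behavior on scenes whose stands exceed the 5 ha maximum-area
parameter: such stands necessarily split into multiple (pure)
segments, so the automatic count exceeds the true count and the
adjusted Rand index is bounded away from 1 even for a perfect
boundary. This is the parameter set's intended minimum-unit behavior,
not an algorithmic failure; boundary recall is the cleaner indicator
there.

## Plot features

~50 features per plot or 20 m cell: nearest-rank height percentiles
p5..p95 (step 5) separately for first- and last-pulse returns (single
returns count as both), mean first-pulse height above 5 m, first-pulse
height standard deviation, below-1 m return ratios per pulse class,
intensity mean/std/p25/p50/p75 per pulse class, and canopy cover
(first-pulse fraction above 2 m). Features with an empty defining
subset are 0 with a missing flag; a zero-return cell is all-missing and
excluded from aggregation. Features are invariant to point order and
to rigid translation of plot plus points. Constant columns are dropped
from the design matrix with a record.

## Sparse Bayesian regression

Linear in the standardized features with an intercept — the model
selects among LiDAR *variables*, not kernels over samples. Type-II
maximum likelihood: posterior `Σ = (σ⁻²ΦᵀΦ + A)⁻¹`, `μ = σ⁻²ΣΦᵀy`,
`γᵢ = 1 − αᵢΣᵢᵢ`, `αᵢ ← γᵢ/μᵢ²`, `σ² ← ‖y − Φμ‖²/(n − Σγ)`; 1e-10
diagonal jitter; convergence when max |Δ log α| < 1e-6.

Pruning combines two rules: a precision ceiling (default 1e4, the
customary automatic-relevance-determination threshold — irrelevant
features settle at large but finite precisions, so a much looser
ceiling under-prunes) and the evidence-based deletion test
`quality² ≤ sparsity`, evaluated with the stable in-model identities
as `μᵢ² ≤ γᵢΣᵢᵢ`. Only the single least relevant function is deleted
per iteration: with correlated features the statistics are valid for
one removal at a time, and the posterior is refit before the next.
The intercept is never pruned, and pruned features never re-enter.
With pruning disabled and α held at a near-zero constant the
predictions reduce to ordinary least squares (tested to 1e-6).

Leave-one-out validation refits n times; accuracy is reported as R²
(squared Pearson, with the adjusted variant and the exact-t p-value),
RMSE% and Bias% of the measured mean.

## Stand inventory

The labeled raster is tessellated into 20 m cells (cell size must be a
pixel multiple); each cell belongs to the stand owning the majority of
its pixels, ties to the smaller id. Cell features feed the four fitted
models; stand values are cell-area-weighted means — correct for the
intensive parameters H and D and for the per-hectare densities G and
V alike. Evaluation is at plot scale: predictions at the held-out
plots' footprints against the field-measured values.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:

- **stand map**: seeded Voronoi of uniform random centers on the pixel
  grid — contiguous convex-ish stands tiling the scene;
- **regimes**: the default five stands form a chronosequence — a
  treeless shrub stand and four closed-canopy stages (2000/1200/850/700
  stems/ha at DBH 9/16/26/36 cm, power-law allometry `h = a·d^0.72`
  with 1 m height noise, top heights ≈ 8/12/18/25 m). Stem densities
  keep each forest stand internally closed at the 4 m raster scale, so
  within-stand band variation stays below the merge ceilings while
  between-stand contrasts (≥ 4 m height, ≥ 0.1 density) exceed them;
- **trees**: Poisson counts per stand, uniform positions (clustering
  processes are out of scope), truncated-normal DBH (> 2 cm), heights
  truncated above breast height;
- **point cloud**: pulses on a jittered grid at 2 pulses/m²; crowns are
  solid paraboloids (apex at the tree top, base at half height, radius
  0.10 m per cm DBH); a crown hit yields a vegetation first return on
  the highest intersected surface and, with probability 0.35, a ground
  last return; misses yield single ground returns; 0.05 m Gaussian
  sensor noise; per-class Gaussian intensity (ground 70±10,
  vegetation 40±8);
- **terrain**: base + planar slope + a gentle saddle, so height
  normalization is exercised non-trivially;
- **image**: per-class Gaussian radiometry with ≈ 6 sd class
  separation;
- **plots**: 94 random non-overlapping 20 m squares; truths are the
  field formulas applied to the enclosed tree list; empty plots report
  zeros with an explicit flag rather than NaN so tables stay numeric.

What passing tests show — and what they do not: the synthetic scenes
have piecewise-stationary stands, no understory layer, no species
mixtures within a stand, no occlusion beyond first/last returns, no
GPS error on plots and no registration error between image and cloud.
Recovery numbers here are therefore upper bounds on what the same
pipeline achieves on field data; the oracle tests (formulas, filters,
statistics) transfer directly.

## Problem sizes and seeds

Tests and the acceptance script run the full pipeline on the default
512 m scene (128×128 raster, ≈ 0.6 M returns, ≈ 15 k trees, 94 plots)
and use 256 m scenes where several replicates are needed (merge
monotonicity, determinism); these sizes give stable statistics while
keeping the whole suite under a minute of compute. One seed fans out
to per-stage generators via `numpy.random.SeedSequence.spawn`, so every
stage is individually reproducible and repeated runs are
byte-identical. Scene seed 0 — the package-wide default — defines the
reference scene used in the recovery checks.

## Known limitations

- The exact semantics of the original segmentation software's priority
  function, competition threshold and merge statistics are unpublished;
  the readings here are documented switches, not claims about that
  implementation.
- The merge sweep is greedy and order-dependent (ascending id); a
  different sweep order can change counts by a few segments.
- Volume and basal area inherit the density signal only indirectly
  (via canopy cover and intensity), and the linear basis extrapolates
  poorly for plots straddling stand boundaries; their RMSE% is
  accordingly several times that of height.
- G is reported per plot (m²) with a per-hectare variant alongside,
  since the conventional unit of the printed tables is ambiguous.
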