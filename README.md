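# lidarstands

Stand-level forest inventory from airborne LiDAR: automatic forest
stand segmentation by gradient-guided region growing, and stand
parameter estimation by sparse Bayesian regression.

## The problem

Forest stands — contiguous, internally homogeneous management units —
are the basic bookkeeping unit of operational forestry, and their
delineation is usually drawn by hand. Given a classified airborne LiDAR
point cloud and a 3-band aerial image, this package

1. rasterizes the returns into three 4 m bands: canopy **density**
   (fraction of returns above 1 m), **height** (85th-percentile return
   height) and a Gaussian maximum-likelihood **land-cover
   classification** of the image (bare / low vegetation / forest),
   median- and mean-shift-filtered and stacked into the *DHH
   composite*;
2. segments the composite into stands with a gradient + limited
   iterative region-growing algorithm (local gradient minima seed
   regions under a rising admission schedule; regions compete for
   pixels by weighted band dissimilarity) followed by four rounds of
   threshold merging and a 500 m² minimum mapping unit;
3. estimates the four classical stand parameters per 20 m cell from
   plot-calibrated models and aggregates them per stand.

The parameters are, per field plot of N trees with DBH `d_i` (cm) and
height `h_i` (m), basal areas `g_i = π (d_i/200)²`:

- Lorey's mean height `H = Σ h_i g_i / Σ g_i` (m)
- quadratic mean DBH `D = sqrt(Σ d_i² / N)` (cm)
- basal area `G = Σ g_i` (m²)
- stand volume `V = Σ (5.3108582e-5 · d_i^1.778667 · h_i^1.1280516) / 400 × 10⁴` (m³/ha)

The estimation model is a relevance-vector-style sparse Bayesian linear
regression: each of ~50 plot-level LiDAR features (height percentiles
per pulse class, below-1 m return ratios, intensity statistics, canopy
cover) carries its own Gaussian prior precision estimated by type-II
maximum likelihood; irrelevant features are pruned automatically, and
models are checked by leave-one-out validation and by R², RMSE% and
Bias% against held-out plots.

No proprietary data is required: a synthetic-scene module generates
ground-truthed forest mosaics (Voronoi stand maps with contrasting
density/height regimes, power-law DBH–height allometry, a paraboloid
crown discrete-return LiDAR simulation over polynomial terrain,
Gaussian per-class aerial radiometry and square 20 m field plots), so
the entire pipeline runs and is tested end to end from one seed.

## Worked example

```python
from lidarstands.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=0), out_dir="scratch/demo")
print(result.comparison["count_a"], result.comparison["adjusted_rand_index"])
print(result.metrics[["parameter", "r2", "rmse_pct", "bias_pct"]])
```

On the default 512 m × 512 m scene (5 stands, 94 plots of which 60
train and 34 validate) this prints

```
11 0.786398080286185
  parameter        r2   rmse_pct  bias_pct
0         H  0.997968   2.987441 -1.176798
1         D  0.992412   5.340957 -0.844317
2         G  0.942951  23.457982  9.911634
3         V  0.955125  26.505140  9.963810
```

i.e. the five true stands are recovered as 11 segments (automatic
segmentation is deliberately finer than the reference; segments are
>99 % pure and stands larger than the 5 ha maximum-area parameter are
split), and Lorey's height is recovered on the held-out plots with
R² = 0.998 and an RMSE of 3 % of the mean. G and V are noisier because
they depend on stem density, which LiDAR observes only indirectly
through canopy density.

The same stages are available as a CLI for file-based work:

```bash
lidarstands simulate --seed 0 --out scene/
lidarstands rasterize --points scene/points.csv --out rasters/
lidarstands segment --composite dhh/ --group 5 --out stands/
lidarstands run --seed 0 --out full/
```

Segmentation parameter groups 1–7 (band weights, priority function,
competition threshold, merge thresholds) ship as YAML fixtures in
`lidarstands/params/`.

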