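"""Ground-truthed synthetic forest scenes.

Generates the inputs the inventory pipeline consumes — a mosaic of
contiguous stands with contrasting height/density regimes, per-stand
tree lists with a power-law DBH-height allometry, a discrete-return
point cloud (ground + canopy first/last returns with per-class
intensity), a 3-band aerial image with per-class Gaussian radiometry,
and square field plots measured from the tree lists — together with the
ground truth needed to score every downstream stage.

The crown is a solid paraboloid with its apex at the tree top and its
base at half the tree height; a pulse that intersects a crown produces
a first return on the highest crown surface it meets and, with a fixed
penetration probability, a last return on the ground.  Terrain is a
smooth low-order polynomial surface so that height normalization is
exercised non-trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from lidarstands import fieldparams
from lidarstands.fieldparams import PlotMeasurement, StandParameters
from lidarstands.points import PointCloud
from lidarstands.raster import RasterGrid, grid_from_extent

LAND_COVER = ("bare", "low_vegetation", "forest")


@dataclass(frozen=True)
class StandRegime:
    """Structural regime of one stand."""

    stems_per_ha: float
    dbh_mean_cm: float = 20.0
    dbh_sd_cm: float = 3.0
    allometry_a: float = 1.6
    allometry_b: float = 0.72
    height_noise_sd_m: float = 1.0
    crown_radius_factor: float = 0.10  # m of crown radius per cm of DBH
    land_cover: str = "forest"

    def __post_init__(self) -> None:
        if self.stems_per_ha < 0:
            raise ValueError("stem density must be non-negative")
        if self.dbh_sd_cm < 0 or self.height_noise_sd_m < 0:
            raise ValueError("spreads must be non-negative")
        if self.land_cover not in LAND_COVER:
            raise ValueError(f"unknown land cover {self.land_cover!r}")

    def expected_height(self, d_cm: float) -> float:
        return self.allometry_a * d_cm**self.allometry_b


#: Default radiometry: per-class per-band (mean, sd) of the 3-band image.
DEFAULT_RADIOMETRY: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "bare": ((150.0, 130.0, 110.0), (6.0, 6.0, 6.0)),
    "low_vegetation": ((95.0, 125.0, 70.0), (6.0, 6.0, 6.0)),
    "forest": ((45.0, 80.0, 40.0), (6.0, 6.0, 6.0)),
}

#: Per point-class LiDAR intensity (mean, sd).
DEFAULT_INTENSITY = {"ground": (70.0, 10.0), "vegetation": (40.0, 8.0)}

#: Five contrasting regimes forming a chronosequence: a treeless shrub
#: stand and four closed-canopy forest stages (dense young regeneration,
#: pole stage, mature, old growth; top heights roughly 8, 12, 18 and
#: 25 m).  Stem densities keep each forest stand internally
#: closed/homogeneous at the 4 m raster scale while heights and canopy
#: densities contrast strongly between stands.
DEFAULT_REGIMES: tuple[StandRegime, ...] = (
    StandRegime(stems_per_ha=0.0, land_cover="low_vegetation"),
    StandRegime(2000.0, 9.0, 1.5, allometry_a=1.55),
    StandRegime(1200.0, 16.0, 2.5, allometry_a=1.62),
    StandRegime(850.0, 26.0, 3.5, allometry_a=1.73),
    StandRegime(700.0, 36.0, 4.0, allometry_a=1.90),
)


@dataclass
class SceneConfig:
    """Full specification of a synthetic scene."""

    extent_m: tuple[float, float] = (512.0, 512.0)
    pixel_size_m: float = 4.0
    n_stands: int = 5
    regimes: Sequence[StandRegime] = DEFAULT_REGIMES
    pulse_density_per_m2: float = 2.0
    ground_penetration_prob: float = 0.35
    sensor_noise_sd_m: float = 0.05
    dem_base_m: float = 1500.0
    dem_slope: tuple[float, float] = (0.03, 0.015)
    dem_curvature_m: float = 8.0
    radiometry: dict = field(default_factory=lambda: dict(DEFAULT_RADIOMETRY))
    intensity: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        for side in (w, h):
            if abs(side / self.pixel_size_m - round(side / self.pixel_size_m)) > 1e-9:
                raise ValueError("extent must be divisible by the pixel size")
        if self.n_stands < 1:
            raise ValueError("need at least one stand")
        if len(self.regimes) != self.n_stands:
            raise ValueError("one regime required per stand")
        if self.pulse_density_per_m2 <= 0:
            raise ValueError("pulse density must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.extent_m[0], self.extent_m[1])


@dataclass
class GroundTruth:
    """Everything the scene generator knows that the pipeline must recover."""

    config: SceneConfig
    stand_grid: RasterGrid  # integer labels 1..n_stands
    trees: pd.DataFrame  # stand_id, x, y, d_cm, h_m, crown_r_m
    dem: RasterGrid
    cloud: PointCloud  # absolute elevations, classified
    image_bands: list[RasterGrid]
    class_grid: RasterGrid  # true land-cover codes (index into LAND_COVER)
    plots: list[PlotMeasurement]
    plot_truths: list[StandParameters]


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(16)[stream])


# ---------------------------------------------------------------------------
# Stand mosaic


def generate_stand_map(config: SceneConfig) -> RasterGrid:
    """Seeded-Voronoi mosaic: pixel labels are the nearest of ``n_stands``
    random centers (ties to the smaller stand id); labels 1..n_stands."""
    rng = _spawn(config.rng_seed, 0)
    grid = grid_from_extent(config.extent, config.pixel_size_m, semantic="labels")
    nrows, ncols = grid.shape
    if config.n_stands > nrows * ncols:
        raise ValueError("more stands than pixels")
    w, h = config.extent_m
    centers = np.column_stack([rng.uniform(0, w, config.n_stands), rng.uniform(0, h, config.n_stands)])
    xs, ys = grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx[..., None] - centers[:, 0]) ** 2 + (gy[..., None] - centers[:, 1]) ** 2
    grid.values = np.argmin(d2, axis=-1).astype(float) + 1.0
    return grid


def stand_areas_ha(stand_grid: RasterGrid) -> dict[int, float]:
    pixel_ha = stand_grid.pixel_size**2 / 10000.0
    labels, counts = np.unique(stand_grid.values.astype(int), return_counts=True)
    return {int(l): float(c) * pixel_ha for l, c in zip(labels, counts)}


# ---------------------------------------------------------------------------
# Tree lists


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    if sd == 0:
        if mean <= lower:
            raise ValueError("degenerate truncated normal below its bound")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size - filled)
        keep = draw[draw > lower]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_tree_list(
    stand_grid: RasterGrid,
    regimes: Sequence[StandRegime],
    rng_seed: int,
) -> pd.DataFrame:
    """Poisson tree counts per stand, uniform positions, truncated-normal
    DBH (> 2 cm) and power-law heights (> 1.3 m)."""
    rng = np.random.default_rng(rng_seed)
    labels = stand_grid.values.astype(int)
    pixel_area_ha = stand_grid.pixel_size**2 / 10000.0
    x0, y0 = stand_grid.origin
    px = stand_grid.pixel_size
    records = []
    for stand_id in np.unique(labels):
        regime = regimes[stand_id - 1]
        rows, cols = np.nonzero(labels == stand_id)
        area_ha = rows.size * pixel_area_ha
        count = int(rng.poisson(regime.stems_per_ha * area_ha))
        if count == 0:
            continue
        # uniform over the stand: pick a pixel, then a point inside it
        pick = rng.integers(0, rows.size, count)
        x = x0 + (cols[pick] + rng.uniform(0, 1, count)) * px
        y = y0 - (rows[pick] + rng.uniform(0, 1, count)) * px
        d = _truncated_normal(rng, regime.dbh_mean_cm, regime.dbh_sd_cm, 2.0, count)
        h_det = regime.allometry_a * d**regime.allometry_b
        noise = rng.normal(0.0, regime.height_noise_sd_m, count) if regime.height_noise_sd_m else np.zeros(count)
        h = h_det + noise
        bad = h <= 1.3
        while np.any(bad):  # re-draw noise for heights at or below breast height
            h[bad] = h_det[bad] + rng.normal(0.0, regime.height_noise_sd_m, int(bad.sum()))
            bad = h <= 1.3
        records.append(
            pd.DataFrame(
                {
                    "stand_id": stand_id,
                    "x": x,
                    "y": y,
                    "d_cm": d,
                    "h_m": h,
                    "crown_r_m": regime.crown_radius_factor * d,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["stand_id", "x", "y", "d_cm", "h_m", "crown_r_m"])
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Terrain and point cloud


def dem_elevation(config: SceneConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth analytic terrain: base + planar slope + a gentle saddle."""
    w, h = config.extent_m
    sx, sy = config.dem_slope
    return (
        config.dem_base_m
        + sx * np.asarray(x)
        + sy * np.asarray(y)
        + config.dem_curvature_m * (np.asarray(x) / w) * (np.asarray(y) / h)
    )


def dem_grid(config: SceneConfig) -> RasterGrid:
    grid = grid_from_extent(config.extent, config.pixel_size_m, semantic="elevation_m")
    xs, ys = grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    grid.values = dem_elevation(config, gx, gy)
    return grid


def synthesize_point_cloud(
    trees: pd.DataFrame,
    config: SceneConfig,
    rng_seed: int,
) -> PointCloud:
    """Discrete-return simulation on a jittered pulse grid.

    A pulse whose ground position falls inside at least one crown
    (solid paraboloid: apex at the tree top, base at half tree height)
    yields a vegetation first return on the highest intersected crown
    surface, plus — with ``ground_penetration_prob`` — a ground last
    return; other pulses yield a single ground return.  All elevations
    include Gaussian sensor noise; intensity is drawn per class.
    """
    rng = np.random.default_rng(rng_seed)
    w, h = config.extent_m
    if w <= 0 or h <= 0:
        raise ValueError("empty extent")
    spacing = 1.0 / np.sqrt(config.pulse_density_per_m2)
    nx, ny = int(w / spacing), int(h / spacing)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    px = (ix.ravel() + rng.uniform(0, 1, ix.size)) * spacing
    py = (iy.ravel() + rng.uniform(0, 1, iy.size)) * spacing
    n_pulse = px.size

    canopy = np.full(n_pulse, -np.inf)
    if len(trees):
        rmax = float(trees["crown_r_m"].max())
        pulse_tree = cKDTree(np.column_stack([px, py]))
        tree_tree = cKDTree(trees[["x", "y"]].to_numpy())
        pairs = pulse_tree.sparse_distance_matrix(tree_tree, rmax, output_type="coo_matrix")
        if pairs.nnz:
            r = pairs.data
            tr = pairs.col
            hts = trees["h_m"].to_numpy()[tr]
            radii = trees["crown_r_m"].to_numpy()[tr]
            inside = r < radii
            surf = hts * (1.0 - 0.5 * (r / np.maximum(radii, 1e-12)) ** 2)
            np.maximum.at(canopy, pairs.row[inside], surf[inside])

    hit = np.isfinite(canopy)
    ground_z = dem_elevation(config, px, py)
    noise = lambda n: rng.normal(0.0, config.sensor_noise_sd_m, n)

    xs, ys, zs, kinds, classes = [], [], [], [], []
    # vegetation first returns
    n_hit = int(hit.sum())
    xs.append(px[hit]); ys.append(py[hit])
    zs.append(ground_z[hit] + canopy[hit] + noise(n_hit))
    kinds.append(np.full(n_hit, "first", dtype=object))
    classes.append(np.full(n_hit, "vegetation", dtype=object))
    # penetrating ground last returns
    pen = hit.copy()
    pen[hit] = rng.uniform(0, 1, n_hit) < config.ground_penetration_prob
    n_pen = int(pen.sum())
    xs.append(px[pen]); ys.append(py[pen])
    zs.append(ground_z[pen] + noise(n_pen))
    kinds.append(np.full(n_pen, "last", dtype=object))
    classes.append(np.full(n_pen, "ground", dtype=object))
    # single ground returns
    miss = ~hit
    n_miss = int(miss.sum())
    xs.append(px[miss]); ys.append(py[miss])
    zs.append(ground_z[miss] + noise(n_miss))
    kinds.append(np.full(n_miss, "only", dtype=object))
    classes.append(np.full(n_miss, "ground", dtype=object))

    cls = np.concatenate(classes)
    intensity = np.empty(cls.size)
    for name, (mu, sd) in config.intensity.items():
        m = cls == name
        intensity[m] = rng.normal(mu, sd, int(m.sum()))
    return PointCloud(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
        intensity, np.concatenate(kinds), cls, normalized=False,
    )


# ---------------------------------------------------------------------------
# Aerial image


def class_code_grid(stand_grid: RasterGrid, regimes: Sequence[StandRegime]) -> RasterGrid:
    """True land-cover codes (index into LAND_COVER) per pixel."""
    labels = stand_grid.values.astype(int)
    codes = np.array([LAND_COVER.index(r.land_cover) for r in regimes])
    out = RasterGrid(codes[labels - 1].astype(float), stand_grid.origin, stand_grid.pixel_size, semantic="class_label")
    return out


def synthesize_aerial_image(
    stand_grid: RasterGrid,
    regimes: Sequence[StandRegime],
    radiometry: dict,
    rng_seed: int,
) -> list[RasterGrid]:
    """3-band image: each pixel's band values are independent normals
    around its land-cover class radiometry."""
    rng = np.random.default_rng(rng_seed)
    labels = stand_grid.values.astype(int)
    covers = [r.land_cover for r in regimes]
    missing = set(covers) - set(radiometry)
    if missing:
        raise ValueError(f"radiometry missing classes: {sorted(missing)}")
    bands = []
    for b in range(3):
        mean_lut = np.array([radiometry[c][0][b] for c in covers])
        sd_lut = np.array([radiometry[c][1][b] for c in covers])
        mu = mean_lut[labels - 1]
        sd = sd_lut[labels - 1]
        vals = mu + (rng.normal(0.0, 1.0, labels.shape) * sd if np.any(sd > 0) else 0.0)
        bands.append(RasterGrid(vals, stand_grid.origin, stand_grid.pixel_size, semantic="image_band"))
    return bands


# ---------------------------------------------------------------------------
# Field plots


def sample_plots(
    trees: pd.DataFrame,
    config: SceneConfig,
    n_plots: int = 94,
    rng_seed: int = 0,
    plot_size_m: float = 20.0,
    max_tries: int | None = None,
) -> tuple[list[PlotMeasurement], list[StandParameters]]:
    """Random non-overlapping axis-aligned square plots; each lists the
    trees whose stem falls inside (half-open box) and carries the true
    H/D/G/V computed from that tree list."""
    rng = np.random.default_rng(rng_seed)
    w, h = config.extent_m
    if plot_size_m > w or plot_size_m > h:
        raise ValueError("plot larger than scene")
    max_tries = max_tries or 1000 * n_plots
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n_plots:
        if tries >= max_tries:
            raise RuntimeError(f"could not place {n_plots} non-overlapping plots")
        tries += 1
        cx = rng.uniform(0, w - plot_size_m)
        cy = rng.uniform(0, h - plot_size_m)
        if all(
            abs(cx - ox) >= plot_size_m or abs(cy - oy) >= plot_size_m
            for ox, oy in placed
        ):
            placed.append((cx, cy))
    tx = trees["x"].to_numpy() if len(trees) else np.empty(0)
    ty = trees["y"].to_numpy() if len(trees) else np.empty(0)
    plots, truths = [], []
    for i, (ox, oy) in enumerate(placed):
        inside = (tx >= ox) & (tx < ox + plot_size_m) & (ty >= oy) & (ty < oy + plot_size_m)
        sub = trees[inside] if len(trees) else trees
        plot = PlotMeasurement(
            plot_id=i,
            d_cm=sub["d_cm"].to_numpy() if len(sub) else np.empty(0),
            h_m=sub["h_m"].to_numpy() if len(sub) else np.empty(0),
            area_m2=plot_size_m**2,
            x=sub["x"].to_numpy() if len(sub) else np.empty(0),
            y=sub["y"].to_numpy() if len(sub) else np.empty(0),
            center=(ox + plot_size_m / 2, oy + plot_size_m / 2),
        )
        plots.append(plot)
        truths.append(fieldparams.stand_parameters(plot))
    return plots, truths


# ---------------------------------------------------------------------------
# Whole scene


def generate_scene(config: SceneConfig | None = None, n_plots: int = 94) -> GroundTruth:
    """Generate the full ground-truthed scene from one config + seed."""
    config = config or SceneConfig()
    stand_grid = generate_stand_map(config)
    trees = generate_tree_list(stand_grid, config.regimes, int(_spawn(config.rng_seed, 1).integers(2**31)))
    cloud = synthesize_point_cloud(trees, config, int(_spawn(config.rng_seed, 2).integers(2**31)))
    bands = synthesize_aerial_image(
        stand_grid, config.regimes, config.radiometry, int(_spawn(config.rng_seed, 3).integers(2**31))
    )
    plots, truths = sample_plots(trees, config, n_plots, int(_spawn(config.rng_seed, 4).integers(2**31)))
    return GroundTruth(
        config=config,
        stand_grid=stand_grid,
        trees=trees,
        dem=dem_grid(config),
        cloud=cloud,
        image_bands=bands,
        class_grid=class_code_grid(stand_grid, config.regimes),
        plots=plots,
        plot_truths=truths,
    )
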