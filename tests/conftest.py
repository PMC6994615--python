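import numpy as np
import pytest

from lidarstands import raster as ras
from lidarstands import synthetic as syn
from lidarstands.points import PointCloud


def make_cloud(x, y, z, intensity=None, kind="only", cls="ground", normalized=False):
    """Convenience point-cloud builder for small hand-made fixtures."""
    x = np.asarray(x, dtype=float)
    n = x.size
    intensity = np.full(n, 50.0) if intensity is None else np.asarray(intensity, float)
    kinds = np.full(n, kind, dtype=object) if isinstance(kind, str) else np.asarray(kind, object)
    classes = np.full(n, cls, dtype=object) if isinstance(cls, str) else np.asarray(cls, object)
    return PointCloud(x, np.asarray(y, float), np.asarray(z, float), intensity, kinds, classes, normalized=normalized)


def make_composite(density, height, classes=None, pixel_size=4.0,
                   density_range=(0.0, 1.0), height_range=None):
    """Aligned DHH composite from plain arrays (full-valid grids)."""
    density = np.asarray(density, dtype=float)
    height = np.asarray(height, dtype=float)
    if classes is None:
        classes = np.zeros_like(density)
    classes = np.asarray(classes, dtype=float)
    origin = (0.0, density.shape[0] * pixel_size)
    dg = ras.RasterGrid(density, origin, pixel_size, semantic="density")
    hg = ras.RasterGrid(height, origin, pixel_size, semantic="height_m")
    cg = ras.RasterGrid(classes, origin, pixel_size, semantic="class_label")
    if height_range is None:
        hi = float(height.max())
        height_range = (0.0, hi if hi > 0 else 1.0)
    return ras.CompositeDHH(dg, hg, cg, density_range=density_range, height_range=height_range)


@pytest.fixture(scope="session")
def small_scene():
    """A 160 m scene with 3 stands, shared across tests that only need
    plausible structured inputs."""
    cfg = syn.SceneConfig(
        extent_m=(160.0, 160.0),
        n_stands=3,
        regimes=(
            syn.StandRegime(stems_per_ha=0.0, land_cover="low_vegetation"),
            syn.StandRegime(1500.0, 12.0, 2.0, allometry_a=1.6),
            syn.StandRegime(800.0, 28.0, 3.5, allometry_a=1.8),
        ),
        rng_seed=42,
    )
    return syn.generate_scene(cfg, n_plots=8)


@pytest.fixture(scope="session")
def small_normalized(small_scene):
    dem = ras.grid_min_dem(small_scene.cloud.ground(), 4.0, small_scene.config.extent)
    return ras.normalize_heights(small_scene.cloud, dem)
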