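"""Rasterization of classified point clouds and the DHH composite.

Grid convention: pixel ``(row, col)`` is 0-based with row 0 at map
north; the grid origin is the *outer* corner of pixel ``(0, 0)`` (i.e.
``(xmin, ymax)``); pixel intervals are half-open so a point on a shared
edge belongs to the pixel with the larger row/col index.  Nodata is a
``-9999`` sentinel, masked in all statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from lidarstands.points import PointCloud

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A georeferenced single-band grid.

    ``origin`` is the map coordinate of the outer (north-west) corner of
    pixel (0, 0); ``semantic`` tags the band meaning (``density`` |
    ``height_m`` | ``class_label`` | ``image_band`` | ``gradient`` |
    ``elevation_m`` | ``labels``).
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    nodata: float = NODATA
    semantic: str = "image_band"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid boundary."""
        x0, y0 = self.origin
        nrows, ncols = self.shape
        return (x0, y0 - nrows * self.pixel_size, x0 + ncols * self.pixel_size, y0)

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.origin == other.origin
            and self.pixel_size == other.pixel_size
        )

    def point_to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col); third array flags in-extent points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - y) / self.pixel_size).astype(int)
        nrows, ncols = self.shape
        ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        return row, col, ok

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x centers (per col) and y centers (per row, north to south)."""
        x0, y0 = self.origin
        nrows, ncols = self.shape
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.pixel_size
        return xs, ys


def grid_from_extent(
    extent: tuple[float, float, float, float],
    pixel_size: float,
    fill: float = NODATA,
    semantic: str = "image_band",
) -> RasterGrid:
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / pixel_size))
    nrows = int(round((ymax - ymin) / pixel_size))
    if ncols <= 0 or nrows <= 0:
        raise ValueError("empty extent")
    values = np.full((nrows, ncols), fill, dtype=float)
    return RasterGrid(values, (xmin, ymax), pixel_size, semantic=semantic)


def _pixel_ids(grid: RasterGrid, cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Flat pixel index of each in-extent point, plus the in-extent mask."""
    row, col, ok = grid.point_to_index(cloud.x, cloud.y)
    ncols = grid.shape[1]
    return row[ok] * ncols + col[ok], ok


def nearest_rank(sorted_values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the k-th smallest with k = ceil(p/100 * n)."""
    n = sorted_values.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    k = max(1, math.ceil(percentile / 100.0 * n))
    return float(sorted_values[k - 1])


# ---------------------------------------------------------------------------
# DEM and height normalization


def grid_min_dem(
    ground: PointCloud,
    cell_size: float,
    extent: tuple[float, float, float, float] | None = None,
) -> RasterGrid:
    """Per-cell minimum ground elevation; empty cells filled by iterative
    8-neighbor averaging until the grid is complete."""
    if len(ground) == 0:
        raise ValueError("no ground points")
    if extent is None:
        pad = 1e-9
        extent = (
            float(ground.x.min()),
            float(ground.y.min()) - pad,
            float(ground.x.max()) + pad,
            float(ground.y.max()),
        )
    dem = grid_from_extent(extent, cell_size, semantic="elevation_m")
    ids, ok = _pixel_ids(dem, ground)
    flat = np.full(dem.values.size, np.inf)
    np.minimum.at(flat, ids, ground.z[ok])
    values = flat.reshape(dem.shape)
    values[np.isinf(values)] = np.nan
    values = _fill_nan_by_neighbors(values)
    dem.values = values
    return dem


def _fill_nan_by_neighbors(values: np.ndarray) -> np.ndarray:
    values = values.copy()
    if not np.any(np.isnan(values)):
        return values
    if np.all(np.isnan(values)):
        raise ValueError("cannot fill a grid with no valid cells")
    kernel = np.ones((3, 3))
    while np.any(np.isnan(values)):
        filled = np.nan_to_num(values, nan=0.0)
        valid = (~np.isnan(values)).astype(float)
        sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
        counts = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
        target = np.isnan(values) & (counts > 0)
        values[target] = sums[target] / counts[target]
    return values


def bilinear_at(grid: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of cell-center values at map coordinates.

    Points must lie inside the outer grid extent; beyond the outer ring
    of cell centers the surface extends with edge values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmin, ymin, xmax, ymax = grid.extent
    if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
        raise ValueError("point outside DEM extent")
    nrows, ncols = grid.shape
    px = grid.pixel_size
    # continuous (col, row) position in cell-center coordinates
    fc = np.clip((x - xmin) / px - 0.5, 0.0, ncols - 1.0)
    fr = np.clip((grid.origin[1] - y) / px - 0.5, 0.0, nrows - 1.0)
    c0 = np.clip(np.floor(fc).astype(int), 0, max(ncols - 2, 0))
    r0 = np.clip(np.floor(fr).astype(int), 0, max(nrows - 2, 0))
    c1 = np.minimum(c0 + 1, ncols - 1)
    r1 = np.minimum(r0 + 1, nrows - 1)
    tx = fc - c0
    ty = fr - r0
    v = grid.values
    return (
        v[r0, c0] * (1 - tx) * (1 - ty)
        + v[r0, c1] * tx * (1 - ty)
        + v[r1, c0] * (1 - tx) * ty
        + v[r1, c1] * tx * ty
    )


def normalize_heights(cloud: PointCloud, dem: RasterGrid) -> PointCloud:
    """Replace elevations by height above the DEM surface (bilinear);
    small negative residuals (>= -0.5 m) are clamped to 0."""
    surface = bilinear_at(dem, cloud.x, cloud.y)
    heights = cloud.z - surface
    return cloud.with_heights(heights)


# ---------------------------------------------------------------------------
# Segmentation bands


def height_percentile_raster(
    cloud: PointCloud,
    extent: tuple[float, float, float, float],
    pixel_size: float = 4.0,
    percentile: float = 85.0,
) -> RasterGrid:
    """Per-pixel nearest-rank height percentile (default p85) of all
    returns in the pixel; pixels without returns are nodata."""
    if not cloud.normalized:
        raise ValueError("points must be height-normalized")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    grid = grid_from_extent(extent, pixel_size, semantic="height_m")
    ids, ok = _pixel_ids(grid, cloud)
    z = cloud.z[ok]
    if ids.size == 0:
        return grid
    order = np.lexsort((z, ids))
    ids_s, z_s = ids[order], z[order]
    uniq, starts = np.unique(ids_s, return_index=True)
    counts = np.diff(np.append(starts, ids_s.size))
    k = np.maximum(1, np.ceil(percentile / 100.0 * counts).astype(int))
    vals = z_s[starts + k - 1]
    flat = grid.values.reshape(-1)
    flat[uniq] = vals
    return grid


def density_raster(
    cloud: PointCloud,
    extent: tuple[float, float, float, float],
    pixel_size: float = 4.0,
    vegetation_height_threshold: float = 1.0,
    mode: str = "fixed",
    percentile: float = 85.0,
) -> RasterGrid:
    """Per-pixel ratio of vegetation returns to all returns, in [0, 1].

    ``mode="fixed"`` (default) counts a return as vegetation when its
    normalized height exceeds ``vegetation_height_threshold`` (1 m).
    ``mode="percentile"`` instead counts returns above the pixel's own
    nearest-rank height percentile.
    """
    if not cloud.normalized:
        raise ValueError("points must be height-normalized")
    grid = grid_from_extent(extent, pixel_size, semantic="density")
    ids, ok = _pixel_ids(grid, cloud)
    z = cloud.z[ok]
    if ids.size == 0:
        return grid
    size = grid.values.size
    total = np.bincount(ids, minlength=size).astype(float)
    if mode == "fixed":
        veg = np.bincount(ids[z > vegetation_height_threshold], minlength=size).astype(float)
    elif mode == "percentile":
        perc = height_percentile_raster(cloud, extent, pixel_size, percentile)
        cutoff = perc.values.reshape(-1)[ids]
        veg = np.bincount(ids[z > cutoff], minlength=size).astype(float)
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    flat = grid.values.reshape(-1)
    nonzero = total > 0
    flat[nonzero] = veg[nonzero] / total[nonzero]
    return grid


# ---------------------------------------------------------------------------
# Raster filters


def median_filter(grid: RasterGrid, window: int = 3) -> RasterGrid:
    """Moving-window median; nodata cells are ignored inside the window
    and preserved at their own location.  Windows are clipped at edges."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    values = np.where(grid.valid_mask(), grid.values, np.nan)
    half = window // 2
    padded = np.pad(values, half, mode="constant", constant_values=np.nan)
    stack = np.stack(
        [
            padded[half + dr : padded.shape[0] - half + dr, half + dc : padded.shape[1] - half + dc]
            for dr in range(-half, half + 1)
            for dc in range(-half, half + 1)
        ]
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    out = np.where(grid.valid_mask(), med, grid.nodata)
    out = np.where(np.isnan(out), grid.nodata, out)
    return replace(grid, values=out)


def mean_shift_filter(
    grid: RasterGrid,
    spatial_radius: float = 2.0,
    spectral_radius: float = 1.0,
    max_iter: int = 20,
    tol: float = 1e-3,
) -> RasterGrid:
    """Edge-preserving iterative smoothing: each pixel moves toward the
    mean of neighbors within ``spatial_radius`` (Euclidean, in pixels)
    whose value differs by at most ``spectral_radius``; plateaus that
    differ by more than the spectral radius are never mixed."""
    if spatial_radius <= 0 or spectral_radius <= 0:
        raise ValueError("radii must be positive")
    valid = grid.valid_mask()
    values = np.where(valid, grid.values, np.nan)
    r = int(math.floor(spatial_radius))
    offsets = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= spatial_radius * spatial_radius
    ]
    for _ in range(max_iter):
        sums = np.zeros_like(values)
        counts = np.zeros_like(values)
        for dr, dc in offsets:
            shifted = _shift_nan(values, dr, dc)
            near = np.abs(shifted - values) <= spectral_radius
            near &= ~np.isnan(shifted)
            sums[near] += shifted[near]
            counts[near] += 1.0
        new = np.where(counts > 0, sums / np.maximum(counts, 1.0), values)
        delta = np.nanmax(np.abs(new - values)) if np.any(valid) else 0.0
        values = new
        if delta <= tol:
            break
    out = np.where(valid, values, grid.nodata)
    return replace(grid, values=out)


def _shift_nan(values: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.full_like(values, np.nan)
    nr, nc = values.shape
    rs_src = slice(max(0, -dr), min(nr, nr - dr))
    cs_src = slice(max(0, -dc), min(nc, nc - dc))
    rs_dst = slice(max(0, dr), min(nr, nr + dr))
    cs_dst = slice(max(0, dc), min(nc, nc + dc))
    out[rs_dst, cs_dst] = values[rs_src, cs_src]
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood classification

#: Land-cover classes in tie-break order (lowest index wins ties).
LAND_COVER_CLASSES = ("bare", "low_vegetation", "forest")


def ml_classify(
    bands: list[RasterGrid] | np.ndarray,
    class_stats: dict[str, tuple[np.ndarray, np.ndarray]],
    class_order: tuple[str, ...] | None = None,
) -> RasterGrid:
    """Per-pixel Gaussian maximum-likelihood classification.

    Each class is modelled as independent normals per band (equal
    priors); a pixel is assigned the class maximizing the product of
    band densities, ties broken by the lowest class index.  Returns a
    ``class_label`` grid of integer codes into ``class_order``.
    """
    if isinstance(bands, np.ndarray):
        arr = np.asarray(bands, dtype=float)
        geom = None
    else:
        geom = bands[0]
        for b in bands[1:]:
            if not geom.same_geometry(b):
                raise ValueError("band geometry mismatch")
        arr = np.stack([b.values for b in bands])
    if class_order is None:
        class_order = tuple(class_stats.keys())
    n_bands = arr.shape[0]
    loglik = np.full((len(class_order),) + arr.shape[1:], -np.inf)
    for ci, name in enumerate(class_order):
        means, sds = class_stats[name]
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        if means.size != n_bands or sds.size != n_bands:
            raise ValueError("class stats arity does not match band count")
        if np.any(sds <= 0):
            raise ValueError("class standard deviations must be positive")
        ll = np.zeros(arr.shape[1:])
        for b in range(n_bands):
            ll += -0.5 * ((arr[b] - means[b]) / sds[b]) ** 2 - np.log(sds[b])
        loglik[ci] = ll
    # argmax returns the first (lowest) index on ties
    labels = np.argmax(np.round(loglik, 12), axis=0).astype(float)
    if geom is not None:
        return replace(geom, values=labels, semantic="class_label")
    return RasterGrid(labels, (0.0, float(arr.shape[1])), 1.0, semantic="class_label")


def kappa_coefficient(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion matrix:
    kappa = (p_o - p_e) / (1 - p_e)."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# DHH composite


@dataclass
class CompositeDHH:
    """Aligned density / height / classification bands with the min-max
    parameters that place density and height on a common [0, 1] scale.

    The classification band is categorical: its "difference" between two
    pixels is 0 when the classes agree and 1 otherwise, and a region's
    class statistic is its modal class (with the modal fraction as
    spread).  Band order everywhere is (density, height, class).
    """

    density: RasterGrid
    height: RasterGrid
    classification: RasterGrid
    density_range: tuple[float, float] = (0.0, 1.0)
    height_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not (
            self.density.same_geometry(self.height)
            and self.density.same_geometry(self.classification)
        ):
            raise ValueError("composite bands must share geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    @property
    def pixel_size(self) -> float:
        return self.density.pixel_size

    def valid_mask(self) -> np.ndarray:
        return (
            self.density.valid_mask()
            & self.height.valid_mask()
            & self.classification.valid_mask()
        )

    def normalized_band(self, index: int) -> np.ndarray:
        """Band ``index`` (0 density, 1 height) min-max scaled to [0, 1];
        index 2 returns the raw integer class labels."""
        if index == 0:
            grid, (lo, hi) = self.density, self.density_range
        elif index == 1:
            grid, (lo, hi) = self.height, self.height_range
        elif index == 2:
            return self.classification.values
        else:
            raise IndexError("composite has 3 bands")
        span = hi - lo
        if span <= 0:
            return np.zeros_like(grid.values)
        out = (grid.values - lo) / span
        return np.where(grid.valid_mask(), np.clip(out, 0.0, 1.0), 0.0)

    def raw_band(self, index: int) -> np.ndarray:
        return (self.density, self.height, self.classification)[index].values


def build_composite(
    density: RasterGrid,
    height: RasterGrid,
    classification: RasterGrid,
    density_range: tuple[float, float] | None = None,
    height_range: tuple[float, float] | None = None,
) -> CompositeDHH:
    """Stack the three segmentation bands, recording min-max ranges for
    the continuous bands (observed ranges unless given explicitly)."""
    if not (density.same_geometry(height) and density.same_geometry(classification)):
        raise ValueError("composite bands must share geometry")

    def observed(grid: RasterGrid) -> tuple[float, float]:
        valid = grid.values[grid.valid_mask()]
        if valid.size == 0:
            return (0.0, 1.0)
        return (float(valid.min()), float(valid.max()))

    return CompositeDHH(
        density,
        height,
        classification,
        density_range=density_range or observed(density),
        height_range=height_range or observed(height),
    )


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O (plain-text raster interchange)


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    xmin, ymin, _, _ = grid.extent
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {xmin:.6f}\nyllcorner {ymin:.6f}\n"
        f"cellsize {grid.pixel_size:.6f}\nNODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path: str | Path, semantic: str = "image_band") -> RasterGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"ASCII grid {path}: shape mismatch")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(values, origin, cell, nodata=header.get("nodata_value", NODATA), semantic=semantic)
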