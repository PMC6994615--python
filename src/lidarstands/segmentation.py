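"""Automatic forest stand segmentation (GARGA).

The algorithm proceeds in two phases on the DHH composite
(density / height / classification bands):

1. *Segmentation*: a band-weighted gradient image is computed; seeds are
   local gradient minima admitted under a rising schedule of levels (the
   priority function); a limited best-first region growing annexes
   4-neighbors whose weighted band dissimilarity to the region mean
   stays below an admission bound derived from the competition
   threshold; seeds accumulate across levels and growth is re-run until
   the last level, after which remaining pixels are attached to the
   least dissimilar adjacent region.
2. *Merging*: four rounds of threshold merging (per-band mean and
   standard-deviation difference ceilings that relax round by round),
   followed by forced absorption of segments below the minimum mapping
   unit.

Continuous bands enter growth in normalized [0, 1] units and merging in
raw units (density fraction, height in metres); the categorical
classification band contributes 0 when two classes agree and 1 when
they differ, and a region's class statistic is its modal class with the
modal fraction as spread.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from shapely import box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from sklearn.metrics import adjusted_rand_score

from lidarstands.raster import CompositeDHH, RasterGrid

NEIGHBORS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the gradient + region-growing phase.

    Band order is (density, height, classification) throughout.
    ``growth_scaling`` selects how the admission bound during growth
    depends on the current priority level: ``"level_indexed"`` (default)
    multiplies the competition threshold by the 1-based level index;
    ``"constant"`` uses the competition threshold unchanged.
    """

    gradient_band_weights: tuple[float, float, float] = (0.3, 0.3, 0.3)
    region_growing_band_weights: tuple[float, float, float] = (0.3, 0.3, 0.3)
    priority_function: tuple[float, ...] = (0.0, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0)
    competition_threshold: float = 0.02
    growth_scaling: str = "level_indexed"
    metric: str = "l1"

    def __post_init__(self) -> None:
        for w in (self.gradient_band_weights, self.region_growing_band_weights):
            if len(w) != 3 or any(v < 0 for v in w) or sum(w) <= 0:
                raise ValueError("band weights must be 3 non-negative reals with positive sum")
        p = self.priority_function
        if len(p) < 1 or p[0] < 0 or abs(p[-1] - 1.0) > 1e-12:
            raise ValueError("priority levels must start >= 0 and end at 1.0")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("priority levels must be strictly ascending")
        if self.competition_threshold <= 0:
            raise ValueError("competition threshold must be positive")
        if self.growth_scaling not in ("level_indexed", "constant"):
            raise ValueError("growth_scaling must be 'level_indexed' or 'constant'")
        if self.metric not in ("l1", "l2"):
            raise ValueError("metric must be 'l1' or 'l2'")

    def admission_bound(self, level_index: int) -> float:
        scale = (level_index + 1) if self.growth_scaling == "level_indexed" else 1.0
        return self.competition_threshold * scale


@dataclass(frozen=True)
class MergeParams:
    """Parameters of the four-round threshold merging phase.

    ``rounds`` holds (mean_thresholds, std_thresholds) per round, one
    threshold per band, in raw band units; thresholds are non-decreasing
    across rounds.  ``maximum_area`` caps a merged segment's area and
    ``small_segment_area`` is the minimum mapping unit (both m^2).
    """

    rounds: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = (
        ((0.05, 1.0, 2.0), (0.0, 1.0, 0.2)),
        ((0.1, 1.5, 2.5), (0.008, 1.5, 0.4)),
        ((0.15, 1.8, 3.0), (0.015, 1.8, 0.6)),
        ((0.2, 2.0, 3.2), (0.02, 2.0, 0.75)),
    )
    band_weights: tuple[float, float, float] = (0.3, 0.3, 0.3)
    maximum_area: float = 50000.0
    small_segment_area: float = 500.0
    #: "increase": the std difference of a candidate merge is the growth
    #: in heterogeneity, std(A+B) - max(std_A, std_B), so a homogeneous
    #: absorption passes the tight printed ceilings regardless of the
    #: segments' sizes while a cross-stand merge is blocked by the mean
    #: gap inflating the merged variance.  "pairwise": |std_A - std_B|.
    std_mode: str = "increase"

    def __post_init__(self) -> None:
        if self.maximum_area <= 0 or self.small_segment_area <= 0:
            raise ValueError("areas must be positive")
        prev_mean = prev_std = (-np.inf,) * 3
        for mean_thr, std_thr in self.rounds:
            if len(mean_thr) != 3 or len(std_thr) != 3:
                raise ValueError("thresholds must have one value per band")
            if any(t < 0 for t in mean_thr + std_thr):
                raise ValueError("thresholds must be non-negative")
            if any(m < p for m, p in zip(mean_thr, prev_mean)) or any(
                s < p for s, p in zip(std_thr, prev_std)
            ):
                raise ValueError("thresholds must be non-decreasing across rounds")
            prev_mean, prev_std = mean_thr, std_thr
        if self.std_mode not in ("increase", "pairwise"):
            raise ValueError("std_mode must be 'increase' or 'pairwise'")


# ---------------------------------------------------------------------------
# Gradient


def weighted_gradient(composite: CompositeDHH, weights: Sequence[float]) -> RasterGrid:
    """Band-weighted gradient magnitude, rescaled to [0, 1] by its max.

    Continuous bands use central differences of the normalized band
    (one-sided at edges); the classification band contributes the 0/1
    class-difference convention.
    """
    if len(weights) != 3:
        raise ValueError("need one weight per band")
    total = np.zeros(composite.shape)
    for b, w in enumerate(weights):
        if w == 0:
            continue
        if b == 2:
            gx, gy = _categorical_diff(composite.raw_band(2))
        else:
            gx, gy = _central_diff(composite.normalized_band(b))
        total += w * np.sqrt(gx**2 + gy**2)
    peak = total.max()
    if peak > 0:
        total = total / peak
    values = np.where(composite.valid_mask(), total, composite.density.nodata)
    return replace(composite.density, values=values, semantic="gradient")


def _central_diff(band: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = np.empty_like(band)
    gy = np.empty_like(band)
    gx[:, 1:-1] = (band[:, 2:] - band[:, :-2]) / 2.0
    gx[:, 0] = band[:, 1] - band[:, 0] if band.shape[1] > 1 else 0.0
    gx[:, -1] = band[:, -1] - band[:, -2] if band.shape[1] > 1 else 0.0
    gy[1:-1, :] = (band[2:, :] - band[:-2, :]) / 2.0
    gy[0, :] = band[1, :] - band[0, :] if band.shape[0] > 1 else 0.0
    gy[-1, :] = band[-1, :] - band[-2, :] if band.shape[0] > 1 else 0.0
    return gx, gy


def _categorical_diff(classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = np.zeros(classes.shape)
    gy = np.zeros(classes.shape)
    if classes.shape[1] > 2:
        gx[:, 1:-1] = 0.5 * (classes[:, 2:] != classes[:, :-2])
    if classes.shape[1] > 1:
        gx[:, 0] = (classes[:, 1] != classes[:, 0]).astype(float)
        gx[:, -1] = (classes[:, -1] != classes[:, -2]).astype(float)
    if classes.shape[0] > 2:
        gy[1:-1, :] = 0.5 * (classes[2:, :] != classes[:-2, :])
    if classes.shape[0] > 1:
        gy[0, :] = (classes[1, :] != classes[0, :]).astype(float)
        gy[-1, :] = (classes[-1, :] != classes[-2, :]).astype(float)
    return gx, gy


# ---------------------------------------------------------------------------
# Seeds


def find_seeds(gradient: RasterGrid, labelmap: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Unassigned pixels that are 3x3 local gradient minima with gradient
    <= level; of each 4-connected equal-valued plateau only the
    row-major-first pixel is kept.  Returned in row-major order."""
    if not 0 <= level <= 1:
        raise ValueError("level must lie in [0, 1]")
    g = gradient.values
    valid = gradient.valid_mask()
    nrows, ncols = g.shape
    candidate = valid & (labelmap == 0) & (g <= level)
    # local minimum within the full 3x3 neighborhood (valid cells only)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(g, np.inf)
            rs_dst = slice(max(0, -dr), min(nrows, nrows - dr))
            cs_dst = slice(max(0, -dc), min(ncols, ncols - dc))
            rs_src = slice(max(0, dr), min(nrows, nrows + dr))
            cs_src = slice(max(0, dc), min(ncols, ncols + dc))
            block = np.where(valid[rs_src, cs_src], g[rs_src, cs_src], np.inf)
            shifted[rs_dst, cs_dst] = block
            candidate &= g <= shifted
    seeds: list[tuple[int, int]] = []
    visited = np.zeros_like(candidate)
    for r, c in zip(*np.nonzero(candidate)):
        if visited[r, c]:
            continue
        # flood the 4-connected equal-valued candidate plateau
        stack = [(r, c)]
        visited[r, c] = True
        val = g[r, c]
        while stack:
            rr, cc = stack.pop()
            for dr, dc in NEIGHBORS4:
                nr, nc = rr + dr, cc + dc
                if (
                    0 <= nr < nrows and 0 <= nc < ncols
                    and candidate[nr, nc] and not visited[nr, nc]
                    and g[nr, nc] == val
                ):
                    visited[nr, nc] = True
                    stack.append((nr, nc))
        seeds.append((int(r), int(c)))
    return seeds


# ---------------------------------------------------------------------------
# Region growing


class _RegionState:
    """Incremental per-region band statistics used during growth."""

    __slots__ = ("count", "sum_d", "sum_h", "class_counts")

    def __init__(self, n_classes: int) -> None:
        self.count = 0
        self.sum_d = 0.0
        self.sum_h = 0.0
        self.class_counts = np.zeros(n_classes, dtype=np.int64)

    def add(self, d: float, h: float, cls: int) -> None:
        self.count += 1
        self.sum_d += d
        self.sum_h += h
        self.class_counts[cls] += 1

    @property
    def mean_d(self) -> float:
        return self.sum_d / self.count

    @property
    def mean_h(self) -> float:
        return self.sum_h / self.count

    @property
    def modal_class(self) -> int:
        return int(np.argmax(self.class_counts))


def _growth_arrays(composite: CompositeDHH) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nd = composite.normalized_band(0)
    nh = composite.normalized_band(1)
    cls = composite.raw_band(2).astype(int)
    return nd, nh, cls


def _dissimilarity(params: SegmentationParams, dd: float, dh: float, dc: float) -> float:
    w0, w1, w2 = params.region_growing_band_weights
    if params.metric == "l1":
        return w0 * abs(dd) + w1 * abs(dh) + w2 * dc
    return float(np.sqrt(w0 * dd * dd + w1 * dh * dh + w2 * dc * dc))


def region_grow(
    composite: CompositeDHH,
    seeds: Iterable[tuple[int, int]],
    params: SegmentationParams,
    labelmap: np.ndarray,
    bound: float | None = None,
) -> np.ndarray:
    """Best-first competitive growth of all regions over 4-neighbors.

    New regions are created at ``seeds`` (which must be unassigned);
    regions already present in ``labelmap`` keep growing.  A frontier
    pixel is annexed by the region with the smallest weighted band
    dissimilarity to the region mean, provided it does not exceed
    ``bound`` (``None`` means unbounded); ties fall to the smaller
    segment id, then row-major pixel order.  The labelmap is modified in
    place and returned.
    """
    nd, nh, cls = _growth_arrays(composite)
    valid = composite.valid_mask()
    nrows, ncols = labelmap.shape
    n_classes = int(cls.max()) + 1 if cls.size else 1
    limit = np.inf if bound is None else bound

    regions: dict[int, _RegionState] = {}
    for sid in np.unique(labelmap):
        if sid <= 0:
            continue
        st = _RegionState(n_classes)
        rows, cols = np.nonzero(labelmap == sid)
        st.count = rows.size
        st.sum_d = float(nd[rows, cols].sum())
        st.sum_h = float(nh[rows, cols].sum())
        st.class_counts = np.bincount(cls[rows, cols], minlength=n_classes).astype(np.int64)
        regions[int(sid)] = st

    next_id = max(regions, default=0) + 1
    for r, c in seeds:
        if not valid[r, c]:
            raise ValueError("seed on nodata pixel")
        if labelmap[r, c] != 0:
            raise ValueError("seed already assigned")
        st = _RegionState(n_classes)
        st.add(nd[r, c], nh[r, c], cls[r, c])
        labelmap[r, c] = next_id
        regions[next_id] = st
        next_id += 1

    heap: list[tuple[float, int, int]] = []

    def push_neighbors(r: int, c: int, sid: int) -> None:
        st = regions[sid]
        for dr, dc in NEIGHBORS4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc] and labelmap[nr, nc] == 0:
                d = _dissimilarity(
                    params,
                    nd[nr, nc] - st.mean_d,
                    nh[nr, nc] - st.mean_h,
                    0.0 if cls[nr, nc] == st.modal_class else 1.0,
                )
                if d <= limit:
                    heapq.heappush(heap, (d, sid, nr * ncols + nc))

    for sid in sorted(regions):
        rows, cols = np.nonzero(labelmap == sid)
        for r, c in zip(rows, cols):
            push_neighbors(int(r), int(c), sid)

    while heap:
        d, sid, flat = heapq.heappop(heap)
        r, c = divmod(flat, ncols)
        if labelmap[r, c] != 0:
            continue
        st = regions[sid]
        current = _dissimilarity(
            params,
            nd[r, c] - st.mean_d,
            nh[r, c] - st.mean_h,
            0.0 if cls[r, c] == st.modal_class else 1.0,
        )
        if current > d + 1e-12:
            if current <= limit:
                heapq.heappush(heap, (current, sid, flat))
            continue
        labelmap[r, c] = sid
        st.add(nd[r, c], nh[r, c], cls[r, c])
        push_neighbors(r, c, sid)
    return labelmap


def iterative_segmentation(composite: CompositeDHH, params: SegmentationParams) -> np.ndarray:
    """Limited iterative region growing over the priority-function levels,
    followed by attachment of any leftover pixels; returns a full
    partition of the valid pixels (labels 1..K)."""
    valid = composite.valid_mask()
    labelmap = np.zeros(composite.shape, dtype=int)
    gradient = weighted_gradient(composite, params.gradient_band_weights)
    any_seed = False
    for i, level in enumerate(params.priority_function):
        seeds = find_seeds(gradient, labelmap, level)
        any_seed = any_seed or bool(seeds)
        if not seeds and labelmap.max() == 0:
            continue
        region_grow(composite, seeds, params, labelmap, bound=params.admission_bound(i))
    if not any_seed:
        raise RuntimeError("no seeds found at any priority level")
    if np.any(valid & (labelmap == 0)):
        region_grow(composite, [], params, labelmap, bound=None)
    return labelmap


# ---------------------------------------------------------------------------
# Segment statistics


@dataclass
class SegmentStats:
    """Per-segment band statistics and 4-adjacency, kept incrementally
    consistent across merges."""

    pixel_area: float
    counts: dict[int, int]
    sum_d: dict[int, float]
    sumsq_d: dict[int, float]
    sum_h: dict[int, float]
    sumsq_h: dict[int, float]
    class_counts: dict[int, np.ndarray]
    neighbors: dict[int, set[int]]

    def ids(self) -> list[int]:
        return sorted(self.counts)

    def area(self, sid: int) -> float:
        return self.counts[sid] * self.pixel_area

    def mean(self, sid: int) -> tuple[float, float]:
        n = self.counts[sid]
        return self.sum_d[sid] / n, self.sum_h[sid] / n

    def std(self, sid: int) -> tuple[float, float]:
        n = self.counts[sid]
        var_d = max(self.sumsq_d[sid] / n - (self.sum_d[sid] / n) ** 2, 0.0)
        var_h = max(self.sumsq_h[sid] / n - (self.sum_h[sid] / n) ** 2, 0.0)
        return float(np.sqrt(var_d)), float(np.sqrt(var_h))

    def modal_class(self, sid: int) -> int:
        return int(np.argmax(self.class_counts[sid]))

    def modal_fraction(self, sid: int) -> float:
        cc = self.class_counts[sid]
        return float(cc.max() / cc.sum())

    def merged_std(self, a: int, b: int) -> tuple[float, float]:
        """Population std of the union of two segments, per continuous band."""
        n = self.counts[a] + self.counts[b]
        out = []
        for sums, sumsqs in ((self.sum_d, self.sumsq_d), (self.sum_h, self.sumsq_h)):
            s = sums[a] + sums[b]
            ss = sumsqs[a] + sumsqs[b]
            out.append(float(np.sqrt(max(ss / n - (s / n) ** 2, 0.0))))
        return out[0], out[1]

    def band_deltas(self, a: int, b: int, std_mode: str = "increase") -> tuple[np.ndarray, np.ndarray]:
        """(mean difference, std difference) per band.

        The class band uses the 0/1 modal-class convention with the
        modal fraction as spread.  ``std_mode="increase"`` measures the
        heterogeneity growth a merge would cause (merged std minus the
        larger member std, floored at 0); ``"pairwise"`` the plain
        |std_a - std_b|.
        """
        ma, mb = self.mean(a), self.mean(b)
        sa, sb = self.std(a), self.std(b)
        pa, pb = self.modal_fraction(a), self.modal_fraction(b)
        dmean_cls = 0.0 if self.modal_class(a) == self.modal_class(b) else 1.0
        if std_mode == "pairwise":
            dstd_d = abs(sa[0] - sb[0])
            dstd_h = abs(sa[1] - sb[1])
            dstd_cls = abs(pa - pb)
        else:
            sm = self.merged_std(a, b)
            dstd_d = max(sm[0] - max(sa[0], sb[0]), 0.0)
            dstd_h = max(sm[1] - max(sa[1], sb[1]), 0.0)
            cc = self.class_counts[a] + self.class_counts[b]
            p_merged = float(cc.max() / cc.sum())
            dstd_cls = max(min(pa, pb) - p_merged, 0.0)
        dmean = np.array([abs(ma[0] - mb[0]), abs(ma[1] - mb[1]), dmean_cls])
        dstd = np.array([dstd_d, dstd_h, dstd_cls])
        return dmean, dstd

    def optimality_score(self, a: int, b: int, weights: Sequence[float], std_mode: str = "increase") -> float:
        dmean, dstd = self.band_deltas(a, b, std_mode)
        return float(sum(w * (m + s) for w, m, s in zip(weights, dmean, dstd)))

    def merge(self, keep: int, absorb: int) -> None:
        self.counts[keep] += self.counts.pop(absorb)
        self.sum_d[keep] += self.sum_d.pop(absorb)
        self.sumsq_d[keep] += self.sumsq_d.pop(absorb)
        self.sum_h[keep] += self.sum_h.pop(absorb)
        self.sumsq_h[keep] += self.sumsq_h.pop(absorb)
        self.class_counts[keep] = self.class_counts[keep] + self.class_counts.pop(absorb)
        for other in self.neighbors.pop(absorb):
            if other == keep:
                continue
            self.neighbors[other].discard(absorb)
            self.neighbors[other].add(keep)
            self.neighbors[keep].add(other)
        self.neighbors[keep].discard(absorb)
        self.neighbors[keep].discard(keep)


def compute_segment_stats(labelmap: np.ndarray, composite: CompositeDHH) -> SegmentStats:
    """Exact per-segment per-band means / population standard deviations
    (raw band units) and symmetric 4-adjacency neighbor sets."""
    valid = composite.valid_mask()
    if np.any(valid & (labelmap == 0)):
        raise ValueError("labelmap must cover all valid pixels")
    d = composite.raw_band(0)
    h = composite.raw_band(1)
    cls = composite.raw_band(2).astype(int)
    labels = np.where(valid, labelmap, 0)
    n_classes = int(cls.max()) + 1 if cls.size else 1
    maxid = int(labels.max())
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=maxid + 1)
    sum_d = np.bincount(flat, weights=d.ravel(), minlength=maxid + 1)
    sumsq_d = np.bincount(flat, weights=(d**2).ravel(), minlength=maxid + 1)
    sum_h = np.bincount(flat, weights=h.ravel(), minlength=maxid + 1)
    sumsq_h = np.bincount(flat, weights=(h**2).ravel(), minlength=maxid + 1)
    cc = np.zeros((maxid + 1, n_classes), dtype=np.int64)
    np.add.at(cc, (flat, cls.ravel()), 1)

    ids = [sid for sid in range(1, maxid + 1) if counts[sid] > 0]
    neighbors: dict[int, set[int]] = {sid: set() for sid in ids}
    for axis in (0, 1):
        a = labels[:-1, :] if axis == 0 else labels[:, :-1]
        b = labels[1:, :] if axis == 0 else labels[:, 1:]
        diff = (a != b) & (a > 0) & (b > 0)
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            neighbors[int(u)].add(int(v))
            neighbors[int(v)].add(int(u))
    return SegmentStats(
        pixel_area=composite.pixel_size**2,
        counts={sid: int(counts[sid]) for sid in ids},
        sum_d={sid: float(sum_d[sid]) for sid in ids},
        sumsq_d={sid: float(sumsq_d[sid]) for sid in ids},
        sum_h={sid: float(sum_h[sid]) for sid in ids},
        sumsq_h={sid: float(sumsq_h[sid]) for sid in ids},
        class_counts={sid: cc[sid].copy() for sid in ids},
        neighbors=neighbors,
    )


# ---------------------------------------------------------------------------
# Merging


def _best_neighbor(
    stats: SegmentStats, sid: int, weights: Sequence[float], std_mode: str = "increase"
) -> int | None:
    best, best_score = None, np.inf
    for other in sorted(stats.neighbors[sid]):
        score = stats.optimality_score(sid, other, weights, std_mode)
        if score < best_score - 1e-15:
            best, best_score = other, score
    return best


def merge_pass(
    labelmap: np.ndarray,
    stats: SegmentStats,
    round_thresholds: tuple[Sequence[float], Sequence[float]],
    merge_params: MergeParams,
) -> np.ndarray:
    """One merging sweep in ascending segment-id order.

    For each surviving segment, its most optimal neighbor (smallest
    band-weighted |delta mean| + |delta std| sum) is merged in when every
    band's mean and std difference is at or below the round's
    thresholds and the combined area does not exceed ``maximum_area``.
    A segment may equally merge with a neighbor for which it is itself
    the most optimal one (mutual-optimality direction).  Statistics are
    recomputed (incrementally) after each accepted merge.  The labelmap
    is updated in place.
    """
    mean_thr, std_thr = round_thresholds
    if len(mean_thr) != 3 or len(std_thr) != 3:
        raise ValueError("thresholds must have one value per band")
    parent = {sid: sid for sid in stats.ids()}

    def find(sid: int) -> int:
        while parent[sid] != sid:
            parent[sid] = parent[parent[sid]]
            sid = parent[sid]
        return sid

    def admissible(a: int, b: int) -> bool:
        dmean, dstd = stats.band_deltas(a, b, merge_params.std_mode)
        if np.any(dmean > np.asarray(mean_thr)) or np.any(dstd > np.asarray(std_thr)):
            return False
        return stats.area(a) + stats.area(b) <= merge_params.maximum_area

    for sid in stats.ids():
        if find(sid) != sid:
            continue
        best = _best_neighbor(stats, sid, merge_params.band_weights, merge_params.std_mode)
        if best is None:
            continue
        partner = None
        if admissible(sid, best):
            partner = best
        else:
            # reverse direction: a neighbor whose own optimum is this segment
            for other in sorted(stats.neighbors[sid]):
                if (
                    _best_neighbor(stats, other, merge_params.band_weights, merge_params.std_mode) == sid
                    and admissible(sid, other)
                ):
                    partner = other
                    break
        if partner is None:
            continue
        keep, absorb = (sid, partner) if sid < partner else (partner, sid)
        stats.merge(keep, absorb)
        parent[absorb] = keep
    _relabel(labelmap, parent, find)
    return labelmap


def enforce_min_area(
    labelmap: np.ndarray,
    stats: SegmentStats,
    small_segment_area: float,
    band_weights: Sequence[float] = (0.3, 0.3, 0.3),
) -> np.ndarray:
    """Absorb every segment below the minimum mapping unit into its most
    optimal neighbor (threshold tests waived), smallest first."""
    parent = {sid: sid for sid in stats.ids()}

    def find(sid: int) -> int:
        while parent[sid] != sid:
            parent[sid] = parent[parent[sid]]
            sid = parent[sid]
        return sid

    while True:
        small = [
            sid for sid in stats.ids()
            if stats.area(sid) < small_segment_area and stats.neighbors[sid]
        ]
        if not small or len(stats.ids()) <= 1:
            break
        sid = min(small, key=lambda s: (stats.area(s), s))
        best = _best_neighbor(stats, sid, band_weights)
        if best is None:
            break
        keep, absorb = (sid, best) if sid < best else (best, sid)
        stats.merge(keep, absorb)
        parent[absorb] = keep
    _relabel(labelmap, parent, find)
    return labelmap


def _relabel(labelmap: np.ndarray, parent: dict[int, int], find) -> None:
    if all(k == v for k, v in parent.items()):
        return
    maxid = int(labelmap.max())
    lut = np.arange(maxid + 1)
    for sid in parent:
        lut[sid] = find(sid)
    labelmap[:] = lut[labelmap]


def compact_labels(labelmap: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ids 1..K preserving ascending id order."""
    ids = np.unique(labelmap)
    ids = ids[ids > 0]
    lut = np.zeros(int(labelmap.max()) + 1, dtype=int)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[labelmap]


# ---------------------------------------------------------------------------
# Full segmentation and comparison


def polygonize_labels(labelmap: np.ndarray, grid: RasterGrid) -> dict[int, BaseGeometry]:
    """Pixel-boundary polygons per segment id (union of pixel squares)."""
    x0, y0 = grid.origin
    px = grid.pixel_size
    out: dict[int, BaseGeometry] = {}
    for sid in np.unique(labelmap):
        if sid <= 0:
            continue
        rows, cols = np.nonzero(labelmap == sid)
        boxes = shapely_box(
            x0 + cols * px, y0 - (rows + 1) * px, x0 + (cols + 1) * px, y0 - rows * px
        )
        out[int(sid)] = unary_union(boxes)
    return out


def segment_stands(
    composite: CompositeDHH,
    params: SegmentationParams,
    merge_params: MergeParams,
) -> tuple[RasterGrid, dict[int, BaseGeometry], SegmentStats]:
    """Full GARGA segmentation: iterative growing, four merge rounds,
    minimum-mapping-unit enforcement, label compaction, polygonization."""
    labelmap = iterative_segmentation(composite, params)
    stats = compute_segment_stats(labelmap, composite)
    for round_thresholds in merge_params.rounds:
        # each threshold round is swept until no further merge occurs
        while True:
            before = len(stats.counts)
            merge_pass(labelmap, stats, round_thresholds, merge_params)
            if len(stats.counts) == before:
                break
    enforce_min_area(labelmap, stats, merge_params.small_segment_area, merge_params.band_weights)
    labelmap = compact_labels(labelmap)
    grid = replace(composite.density, values=labelmap.astype(float), semantic="labels")
    polygons = polygonize_labels(labelmap, grid)
    final_stats = compute_segment_stats(labelmap, composite)
    return grid, polygons, final_stats


def compare_segmentations(labelmap_a: np.ndarray, labelmap_b: np.ndarray) -> dict:
    """Agreement report between two label maps on the same grid: segment
    counts, adjusted Rand index and boundary precision/recall at
    1-pixel tolerance (map A scored against reference map B)."""
    a = np.asarray(labelmap_a, dtype=int)
    b = np.asarray(labelmap_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("geometry mismatch")
    count_a = int(np.unique(a[a > 0]).size)
    count_b = int(np.unique(b[b > 0]).size)
    ari = float(adjusted_rand_score(b.ravel(), a.ravel()))
    from scipy import ndimage

    def boundary(lm: np.ndarray) -> np.ndarray:
        e = np.zeros(lm.shape, dtype=bool)
        e[:-1, :] |= lm[:-1, :] != lm[1:, :]
        e[:, :-1] |= lm[:, :-1] != lm[:, 1:]
        return e

    ba, bb = boundary(a), boundary(b)
    if not ba.any() and not bb.any():
        precision = recall = 1.0
    else:
        dil_b = ndimage.binary_dilation(bb, structure=np.ones((3, 3)))
        dil_a = ndimage.binary_dilation(ba, structure=np.ones((3, 3)))
        precision = float(np.sum(ba & dil_b) / ba.sum()) if ba.any() else 1.0
        recall = float(np.sum(bb & dil_a) / bb.sum()) if bb.any() else 1.0
    return {
        "count_a": count_a,
        "count_b": count_b,
        "count_difference": count_a - count_b,
        "adjusted_rand_index": ari,
        "boundary_precision": precision,
        "boundary_recall": recall,
    }
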