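"""Plot-level LiDAR predictor variables.

The feature set covers the categories used in area-based inventory:
height percentiles (nearest-rank, p5..p95 by 5) separately for
first-pulse and last-pulse returns, the mean first-pulse height above
5 m, the standard deviation of first-pulse heights, the below-1 m
return ratios per pulse class, intensity statistics per pulse class,
and canopy cover.  Returns flagged ``only`` (single-return pulses)
count as both first and last pulse.

Features whose defining subset is empty (e.g. no first-pulse return
above 5 m) are reported as 0 with a missing flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lidarstands.fieldparams import PlotMeasurement
from lidarstands.points import PointCloud
from lidarstands.raster import nearest_rank

PERCENTILES = tuple(range(5, 100, 5))
HIGH_VEGETATION_CUTOFF_M = 5.0
LOW_RETURN_CUTOFF_M = 1.0
CANOPY_COVER_CUTOFF_M = 2.0
INTENSITY_PERCENTILES = (25, 50, 75)


def _manifest() -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    for pulse in ("first", "last"):
        for p in PERCENTILES:
            rows.append(
                {
                    "name": f"h_p{p}_{pulse}",
                    "definition": f"nearest-rank {p}th height percentile of {pulse}-pulse returns",
                    "units": "m",
                }
            )
    rows.append(
        {
            "name": "h_mean_first_above5",
            "definition": f"mean height of first-pulse returns above {HIGH_VEGETATION_CUTOFF_M:g} m",
            "units": "m",
        }
    )
    rows.append(
        {"name": "h_std_first", "definition": "standard deviation of first-pulse heights", "units": "m"}
    )
    for pulse in ("first", "last"):
        rows.append(
            {
                "name": f"frac_{pulse}_below1",
                "definition": f"ratio of {pulse}-pulse returns below {LOW_RETURN_CUTOFF_M:g} m to all {pulse}-pulse returns",
                "units": "fraction",
            }
        )
    for pulse in ("first", "last"):
        rows.append({"name": f"i_mean_{pulse}", "definition": f"mean intensity of {pulse}-pulse returns", "units": "DN"})
        rows.append({"name": f"i_std_{pulse}", "definition": f"intensity standard deviation of {pulse}-pulse returns", "units": "DN"})
        for p in INTENSITY_PERCENTILES:
            rows.append(
                {
                    "name": f"i_p{p}_{pulse}",
                    "definition": f"nearest-rank {p}th intensity percentile of {pulse}-pulse returns",
                    "units": "DN",
                }
            )
    rows.append(
        {
            "name": "canopy_cover",
            "definition": f"fraction of first-pulse returns above {CANOPY_COVER_CUTOFF_M:g} m",
            "units": "fraction",
        }
    )
    return rows


FEATURE_MANIFEST: list[dict[str, str]] = _manifest()
FEATURE_NAMES: tuple[str, ...] = tuple(r["name"] for r in FEATURE_MANIFEST)


@dataclass
class PlotFeatureVector:
    values: pd.Series  # indexed by FEATURE_NAMES
    missing: pd.Series  # bool, same index


def compute_plot_features(cloud: PointCloud) -> PlotFeatureVector:
    """Feature vector of the returns inside one plot (already clipped).

    A plot with zero returns yields an all-missing vector.
    """
    if not cloud.normalized and len(cloud):
        raise ValueError("points must be height-normalized")
    values = pd.Series(0.0, index=list(FEATURE_NAMES))
    missing = pd.Series(False, index=list(FEATURE_NAMES))

    pulses = {"first": cloud.first_pulse(), "last": cloud.last_pulse()}

    def put(name: str, sample: np.ndarray, fn) -> None:
        if sample.size == 0:
            missing[name] = True
        else:
            values[name] = float(fn(sample))

    for pulse, sub in pulses.items():
        z = np.sort(sub.z)
        inten = np.sort(sub.intensity)
        for p in PERCENTILES:
            put(f"h_p{p}_{pulse}", z, lambda s, p=p: nearest_rank(s, p))
        put(f"frac_{pulse}_below1", sub.z, lambda s: np.mean(s < LOW_RETURN_CUTOFF_M))
        put(f"i_mean_{pulse}", sub.intensity, np.mean)
        put(f"i_std_{pulse}", sub.intensity, np.std)
        for p in INTENSITY_PERCENTILES:
            put(f"i_p{p}_{pulse}", inten, lambda s, p=p: nearest_rank(s, p))

    first = pulses["first"]
    put("h_mean_first_above5", first.z[first.z > HIGH_VEGETATION_CUTOFF_M], np.mean)
    put("h_std_first", first.z, np.std)
    put("canopy_cover", first.z, lambda s: np.mean(s > CANOPY_COVER_CUTOFF_M))
    return PlotFeatureVector(values=values, missing=missing)


@dataclass
class FeatureTable:
    """Design matrix of plot feature vectors plus standardization state."""

    X: pd.DataFrame  # raw feature values, one row per plot
    missing: pd.DataFrame  # bool mask, same shape
    means: pd.Series
    sds: pd.Series
    dropped: list[str]  # constant features removed from X

    def standardized(self) -> pd.DataFrame:
        return (self.X - self.means) / self.sds


def plot_bounds(plot: PlotMeasurement) -> tuple[float, float, float, float]:
    if plot.center is None:
        raise ValueError("plot has no recorded center")
    half = float(np.sqrt(plot.area_m2)) / 2.0
    cx, cy = plot.center
    return (cx - half, cy - half, cx + half, cy + half)


def feature_matrix(plots: list[PlotMeasurement], cloud: PointCloud) -> FeatureTable:
    """One feature row per plot (half-open square clip of the cloud),
    with per-feature standardization parameters; constant features are
    dropped and recorded."""
    ids = [p.plot_id for p in plots]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plot ids")
    rows, miss = [], []
    for plot in plots:
        xmin, ymin, xmax, ymax = plot_bounds(plot)
        fv = compute_plot_features(cloud.clip_box(xmin, ymin, xmax, ymax))
        rows.append(fv.values)
        miss.append(fv.missing)
    X = pd.DataFrame(rows, index=ids)
    missing = pd.DataFrame(miss, index=ids)
    sds = X.std(ddof=0)
    dropped = list(X.columns[sds == 0.0])
    X = X.drop(columns=dropped)
    missing = missing.drop(columns=dropped)
    means = X.mean()
    sds = X.std(ddof=0)
    return FeatureTable(X=X, missing=missing, means=means, sds=sds, dropped=dropped)
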