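"""LiDAR point-cloud container and XYZ CSV I/O.

A :class:`PointCloud` holds one row per return with coordinates,
intensity, return position within the pulse (``first`` / ``last`` /
``only`` — a single-return pulse is both its first and last return) and
a ground/vegetation class.  Heights may be absolute elevations or
heights above ground; ``normalized`` records which.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

RETURN_KINDS = ("first", "last", "only")
POINT_CLASSES = ("ground", "low_vegetation", "vegetation", "noise")

#: Normalized heights may dip slightly below ground due to sensor noise.
MIN_NORMALIZED_HEIGHT = -0.5


@dataclass
class PointCloud:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray
    return_kind: np.ndarray  # array of str, values in RETURN_KINDS
    cls: np.ndarray  # array of str, values in POINT_CLASSES
    normalized: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.return_kind = np.asarray(self.return_kind, dtype=object)
        self.cls = np.asarray(self.cls, dtype=object)
        n = self.x.size
        for arr, name in [
            (self.y, "y"), (self.z, "z"), (self.intensity, "intensity"),
            (self.return_kind, "return_kind"), (self.cls, "cls"),
        ]:
            if arr.size != n:
                raise ValueError(f"column {name} has length {arr.size}, expected {n}")
        for arr in (self.x, self.y, self.z):
            if n and not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")
        bad = set(np.unique(self.return_kind)) - set(RETURN_KINDS)
        if bad:
            raise ValueError(f"unknown return kinds: {sorted(bad)}")
        bad = set(np.unique(self.cls)) - set(POINT_CLASSES)
        if bad:
            raise ValueError(f"unknown point classes: {sorted(bad)}")
        if self.normalized and n and self.z.min() < MIN_NORMALIZED_HEIGHT:
            raise ValueError("normalized heights below -0.5 m tolerance")

    def __len__(self) -> int:
        return int(self.x.size)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask], self.intensity[mask],
            self.return_kind[mask], self.cls[mask], normalized=self.normalized,
        )

    def ground(self) -> "PointCloud":
        return self.subset(self.cls == "ground")

    def first_pulse(self) -> "PointCloud":
        """Returns participating as the first return of their pulse."""
        return self.subset(np.isin(self.return_kind, ("first", "only")))

    def last_pulse(self) -> "PointCloud":
        return self.subset(np.isin(self.return_kind, ("last", "only")))

    def clip_box(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "PointCloud":
        """Half-open box [xmin, xmax) x [ymin, ymax)."""
        m = (self.x >= xmin) & (self.x < xmax) & (self.y >= ymin) & (self.y < ymax)
        return self.subset(m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x, "y": self.y, "z": self.z,
                "intensity": self.intensity,
                "return_kind": self.return_kind.astype(str),
                "class": self.cls.astype(str),
            }
        )

    def with_heights(self, heights: np.ndarray) -> "PointCloud":
        clamped = np.maximum(np.asarray(heights, dtype=float), 0.0)
        return replace(self, z=clamped, normalized=True)


def write_csv(cloud: PointCloud, path: str | Path) -> None:
    df = cloud.to_frame()
    df.insert(0, "normalized", int(cloud.normalized))
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path: str | Path) -> PointCloud:
    df = pd.read_csv(path)
    required = {"x", "y", "z", "intensity", "return_kind", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"point CSV {path} missing columns: {sorted(missing)}")
    normalized = bool(df["normalized"].iloc[0]) if "normalized" in df and len(df) else False
    return PointCloud(
        df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy(),
        df["intensity"].to_numpy(),
        df["return_kind"].to_numpy(dtype=object),
        df["class"].to_numpy(dtype=object),
        normalized=normalized,
    )
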