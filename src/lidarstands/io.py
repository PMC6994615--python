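"""Plain-text interchange: GeoJSON polygons, tree/plot CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from lidarstands.fieldparams import PlotMeasurement


def write_geojson(
    polygons: dict[int, BaseGeometry],
    path: str | Path,
    properties: dict[int, dict] | None = None,
    crs: str | None = None,
) -> None:
    feats = []
    for sid in sorted(polygons):
        props = {"stand_id": sid}
        if properties and sid in properties:
            props.update(properties[sid])
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(polygons[sid])}
        )
    doc: dict = {"type": "FeatureCollection", "features": feats}
    if crs:
        doc["crs"] = {"type": "name", "properties": {"name": crs}}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_geojson(path: str | Path) -> dict[int, BaseGeometry]:
    doc = json.loads(Path(path).read_text())
    return {
        int(f["properties"]["stand_id"]): shape(f["geometry"])
        for f in doc["features"]
    }


def write_tree_csv(plots: list[PlotMeasurement], path: str | Path) -> None:
    """Long-format plot tree lists: plot_id, tree_id, d_cm, h_m."""
    rows = []
    for plot in plots:
        for i in range(plot.n):
            rows.append(
                {"plot_id": plot.plot_id, "tree_id": i, "d_cm": plot.d_cm[i], "h_m": plot.h_m[i]}
            )
    pd.DataFrame(rows, columns=["plot_id", "tree_id", "d_cm", "h_m"]).to_csv(path, index=False)


def read_tree_csv(path: str | Path, area_m2: float = 400.0) -> list[PlotMeasurement]:
    df = pd.read_csv(path)
    required = {"plot_id", "d_cm", "h_m"}
    if not required <= set(df.columns):
        raise ValueError(f"tree CSV {path} must have columns {sorted(required)}")
    plots = []
    for pid, sub in df.groupby("plot_id", sort=True):
        plots.append(
            PlotMeasurement(pid, sub["d_cm"].to_numpy(), sub["h_m"].to_numpy(), area_m2=area_m2)
        )
    return plots


def write_plot_csv(plots: list[PlotMeasurement], path: str | Path) -> None:
    """Plot footprints: plot_id, center x/y, area."""
    rows = [
        {
            "plot_id": p.plot_id,
            "center_x": p.center[0] if p.center else np.nan,
            "center_y": p.center[1] if p.center else np.nan,
            "area_m2": p.area_m2,
            "n_trees": p.n,
        }
        for p in plots
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
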