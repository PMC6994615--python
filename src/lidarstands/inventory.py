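"""Stand-level inventory: 20 m cell tessellation over the segmentation,
per-cell prediction with the fitted models, aggregation to stands, and
plot-scale accuracy evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lidarstands import features as feat
from lidarstands import fieldparams
from lidarstands.fieldparams import PlotMeasurement
from lidarstands.points import PointCloud
from lidarstands.raster import RasterGrid
from lidarstands.rvm import RVMModel, rvm_predict

PARAMETER_ORDER = ("H", "D", "G", "V")
PARAMETER_UNITS = {"H": "m", "D": "cm", "G": "m2", "V": "m3/ha"}


@dataclass
class InventoryCell:
    cell_id: int
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    stand_id: int
    features: pd.Series | None = None
    missing: pd.Series | None = None
    predictions: dict[str, float] = field(default_factory=dict)
    predicted: bool = False

    @property
    def area_m2(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)


def tessellate_cells(label_grid: RasterGrid, cell_size: float = 20.0) -> list[InventoryCell]:
    """Regular grid of square cells over the labeled scene; each cell is
    owned by the stand holding the majority of its pixels (ties to the
    smaller stand id).  Cells lying wholly on unlabeled pixels are
    dropped."""
    px = label_grid.pixel_size
    ratio = cell_size / px
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("cell size must be a multiple of the raster pixel size")
    k = int(round(ratio))
    labels = label_grid.values.astype(int)
    nrows, ncols = labels.shape
    x0, y0 = label_grid.origin
    cells: list[InventoryCell] = []
    cid = 0
    for cr in range(nrows // k):
        for cc in range(ncols // k):
            block = labels[cr * k : (cr + 1) * k, cc * k : (cc + 1) * k]
            counts = np.bincount(block.ravel())
            counts[0] = 0  # unlabeled pixels never own a cell
            if counts.sum() == 0:
                continue
            owner = int(np.argmax(counts))  # first (smallest) id wins ties
            xmin = x0 + cc * k * px
            ymax = y0 - cr * k * px
            cells.append(
                InventoryCell(
                    cell_id=cid,
                    bounds=(xmin, ymax - cell_size, xmin + cell_size, ymax),
                    stand_id=owner,
                )
            )
            cid += 1
    return cells


def predict_cells(
    cells: list[InventoryCell],
    cloud: PointCloud,
    models: dict[str, RVMModel],
) -> list[InventoryCell]:
    """Compute each cell's feature vector from its points and predict all
    stand parameters; cells whose features are all missing (no returns)
    are flagged unpredicted.  Models must share one feature manifest."""
    manifests = {tuple(m.feature_names) for m in models.values()}
    if len(manifests) != 1:
        raise ValueError("models disagree on the feature manifest")
    for cell in cells:
        sub = cloud.clip_box(*cell.bounds)
        fv = feat.compute_plot_features(sub)
        cell.features = fv.values
        cell.missing = fv.missing
        if fv.missing.all():
            cell.predicted = False
            continue
        row = fv.values.to_frame().T
        for name, model in models.items():
            mean, _ = rvm_predict(model, row)
            cell.predictions[name] = float(mean[0])
        cell.predicted = True
    return cells


def aggregate_to_stands(cells: list[InventoryCell]) -> pd.DataFrame:
    """Cell-area-weighted stand aggregates of the predicted parameters.

    H and D are intensive means; G and V are per-area densities, so the
    area-weighted mean is their stand value too.  Stands without any
    predicted cell are reported with ``missing=True``.
    """
    stand_ids = sorted({c.stand_id for c in cells})
    rows = []
    for sid in stand_ids:
        mine = [c for c in cells if c.stand_id == sid]
        done = [c for c in mine if c.predicted]
        area = sum(c.area_m2 for c in mine)
        row: dict[str, object] = {
            "stand_id": sid,
            "area_m2": area,
            "n_cells": len(mine),
            "n_cells_used": len(done),
            "missing": not done,
        }
        weights = np.array([c.area_m2 for c in done])
        for name in PARAMETER_ORDER:
            if done:
                vals = np.array([c.predictions[name] for c in done])
                row[name] = float(np.average(vals, weights=weights))
            else:
                row[name] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def predict_plots(
    plots: list[PlotMeasurement],
    cloud: PointCloud,
    models: dict[str, RVMModel],
) -> pd.DataFrame:
    """Model predictions at field-plot footprints (for evaluation)."""
    table = feat.feature_matrix(plots, cloud)
    out = pd.DataFrame(index=table.X.index)
    for name, model in models.items():
        mean, _ = rvm_predict(model, table.X)
        out[name] = mean
    out.index.name = "plot_id"
    return out


def evaluate_inventory(predicted: pd.DataFrame, measured: pd.DataFrame) -> pd.DataFrame:
    """Accuracy table (one row per parameter H, D, G, V): R^2, adjusted
    R^2, correlation p-value, RMSE% and Bias% of predictions against
    plot measurements matched on plot id."""
    if set(predicted.index) != set(measured.index):
        raise ValueError("plot ids of predictions and measurements do not match")
    if len(measured) < 3:
        raise ValueError("need at least 3 matched plots")
    measured = measured.loc[predicted.index]
    rows = []
    for name in PARAMETER_ORDER:
        m = measured[name].to_numpy(dtype=float)
        e = predicted[name].to_numpy(dtype=float)
        r2 = fieldparams.r_squared(m, e)
        rows.append(
            {
                "parameter": name,
                "units": PARAMETER_UNITS[name],
                "r2": r2.r2,
                "adjusted_r2": r2.adjusted,
                "p_value": r2.p_value,
                "rmse_pct": fieldparams.rmse(m, e).percent,
                "bias_pct": fieldparams.bias(m, e).percent,
            }
        )
    return pd.DataFrame(rows)


def measured_table(plots: list[PlotMeasurement]) -> pd.DataFrame:
    """Plot-id-indexed table of field-measured H, D, G, V."""
    rows = []
    for plot in plots:
        sp = fieldparams.stand_parameters(plot)
        rows.append({"plot_id": plot.plot_id, "H": sp.H, "D": sp.D, "G": sp.G, "V": sp.V, "N": plot.n, "empty": sp.empty})
    return pd.DataFrame(rows).set_index("plot_id")
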