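"""Stand-parameter formulas and accuracy statistics.

Implements the classical plot summaries used in area-based forest
inventory: Lorey's mean height ``H`` (basal-area-weighted mean height,
m), quadratic mean DBH ``D`` (cm), basal area ``G`` (m^2 per plot, with
a per-hectare variant) and stand volume ``V`` (m^3/ha) from a
two-parameter per-tree power model, plus the evaluation statistics
RMSE/RMSE%, Bias/Bias% and the squared Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _stats

#: Per-tree stem volume model ``v = c0 * d^exp_d * h^exp_h`` with d in cm
#: and h in m; plot volumes are divided by the plot area (m^2) and scaled
#: to a hectare.
VOLUME_C0 = 0.000053108582
VOLUME_EXP_D = 1.778667
VOLUME_EXP_H = 1.1280516
DEFAULT_PLOT_AREA_M2 = 400.0
PER_HA_MULTIPLIER = 10000.0


@dataclass(frozen=True)
class VolumeModelCoefficients:
    """Coefficients of the per-tree stem volume power model."""

    c0: float = VOLUME_C0
    exp_d: float = VOLUME_EXP_D
    exp_h: float = VOLUME_EXP_H
    plot_area_divisor: float = DEFAULT_PLOT_AREA_M2
    per_ha_multiplier: float = PER_HA_MULTIPLIER


DEFAULT_VOLUME_MODEL = VolumeModelCoefficients()


@dataclass
class PlotMeasurement:
    """A field plot: per-tree DBH (cm) and height (m) plus plot geometry.

    ``d_cm[i] > 0`` and ``h_m[i] > 1.3`` (breast height) are required for
    every tree.  ``x``/``y`` stem positions are optional.
    """

    plot_id: str | int
    d_cm: np.ndarray
    h_m: np.ndarray
    area_m2: float = DEFAULT_PLOT_AREA_M2
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.d_cm = np.asarray(self.d_cm, dtype=float)
        self.h_m = np.asarray(self.h_m, dtype=float)
        if self.d_cm.shape != self.h_m.shape:
            raise ValueError("d_cm and h_m must have equal length")
        if self.area_m2 <= 0:
            raise ValueError("plot area must be positive")
        if self.n and (np.any(self.d_cm <= 0) or np.any(self.h_m <= 1.3)):
            raise ValueError("trees require d > 0 cm and h > 1.3 m")

    @property
    def n(self) -> int:
        """Number of stems N in the plot."""
        return int(self.d_cm.size)


@dataclass
class StandParameters:
    """The four stand parameters of one plot (H m, D cm, G m^2, V m^3/ha)."""

    H: float
    D: float
    G: float
    V: float
    empty: bool = False
    G_per_ha: float = field(default=0.0)


def basal_area_single(d_cm: float, *, literal_cm2: bool = False) -> float:
    """Cross-sectional stem area at breast height for one tree.

    The diameter is recorded in cm; the conventional unit of basal area
    is m^2, so the default converts (``g = pi * (d/200)^2``).  With
    ``literal_cm2=True`` the formula is evaluated without unit
    conversion and returns cm^2 (audit variant).
    """
    if d_cm <= 0:
        raise ValueError("DBH must be positive")
    if literal_cm2:
        return math.pi * (d_cm / 2.0) ** 2
    return math.pi * (d_cm / 200.0) ** 2


def basal_areas(plot: PlotMeasurement, *, literal_cm2: bool = False) -> np.ndarray:
    """Vector of per-tree basal areas g_i for a plot."""
    if np.any(plot.d_cm <= 0):
        raise ValueError("DBH must be positive")
    denom = 2.0 if literal_cm2 else 200.0
    return np.pi * (plot.d_cm / denom) ** 2


def lorey_height(plot: PlotMeasurement) -> tuple[float, bool]:
    """Basal-area-weighted mean height H = sum(h_i g_i) / sum(g_i).

    Returns ``(H, empty)``; empty plots yield ``(0.0, True)`` so that
    downstream tables stay numeric.
    """
    if plot.n == 0:
        return 0.0, True
    g = basal_areas(plot)
    return float(np.sum(plot.h_m * g) / np.sum(g)), False


def quadratic_mean_dbh(plot: PlotMeasurement) -> tuple[float, bool]:
    """Quadratic mean DBH, D = sqrt(sum(d_i^2) / N) (cm)."""
    if plot.n == 0:
        return 0.0, True
    return float(math.sqrt(np.sum(plot.d_cm**2) / plot.n)), False


def basal_area_total(plot: PlotMeasurement) -> tuple[float, bool]:
    """Plot basal area G = sum(g_i) in m^2 (per plot)."""
    if plot.n == 0:
        return 0.0, True
    return float(np.sum(basal_areas(plot))), False


def stand_volume(
    plot: PlotMeasurement,
    coefficients: VolumeModelCoefficients = DEFAULT_VOLUME_MODEL,
) -> tuple[float, bool]:
    """Stand volume V (m^3/ha) from the per-tree power model.

    Per-tree volumes are summed, divided by the plot area (m^2) and
    scaled to one hectare.  The divisor defaults to the printed 400 m^2
    (20 m plot) but generalizes to the plot's true area.
    """
    if plot.area_m2 <= 0:
        raise ValueError("plot area must be positive")
    if plot.n == 0:
        return 0.0, True
    divisor = (
        coefficients.plot_area_divisor
        if plot.area_m2 == DEFAULT_PLOT_AREA_M2
        else plot.area_m2
    )
    v_tree = coefficients.c0 * plot.d_cm**coefficients.exp_d * plot.h_m**coefficients.exp_h
    return float(np.sum(v_tree) / divisor * coefficients.per_ha_multiplier), False


def stand_parameters(
    plot: PlotMeasurement,
    coefficients: VolumeModelCoefficients = DEFAULT_VOLUME_MODEL,
) -> StandParameters:
    """All four stand parameters of one plot."""
    h, empty = lorey_height(plot)
    d, _ = quadratic_mean_dbh(plot)
    g, _ = basal_area_total(plot)
    v, _ = stand_volume(plot, coefficients)
    g_ha = g / plot.area_m2 * PER_HA_MULTIPLIER
    return StandParameters(H=h, D=d, G=g, V=v, empty=empty, G_per_ha=g_ha)


class ErrorStats(NamedTuple):
    absolute: float
    percent: float


def _pairs(measured: Sequence[float], estimated: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise ValueError("measured and estimated must be equal-length 1-D sequences")
    if m.size < 1:
        raise ValueError("need at least one pair")
    return m, e


def rmse(measured: Sequence[float], estimated: Sequence[float]) -> ErrorStats:
    """Root-mean-square error and its percentage of the measured mean."""
    m, e = _pairs(measured, estimated)
    value = float(np.sqrt(np.mean((m - e) ** 2)))
    mean_m = float(np.mean(m))
    if mean_m == 0:
        raise ValueError("RMSE% undefined: measured mean is zero")
    return ErrorStats(value, value / mean_m * 100.0)


def bias(measured: Sequence[float], estimated: Sequence[float]) -> ErrorStats:
    """Mean signed error (measured - estimated) and its percentage."""
    m, e = _pairs(measured, estimated)
    value = float(np.mean(m - e))
    mean_m = float(np.mean(m))
    if mean_m == 0:
        raise ValueError("Bias% undefined: measured mean is zero")
    return ErrorStats(value, value / mean_m * 100.0)


class RSquared(NamedTuple):
    r2: float
    adjusted: float
    p_value: float


def r_squared(measured: Sequence[float], estimated: Sequence[float], *, p: int = 1) -> RSquared:
    """Squared Pearson correlation, its adjusted variant and the
    correlation p-value (exact t transform)."""
    m, e = _pairs(measured, estimated)
    n = m.size
    if n < 2:
        raise ValueError("R^2 requires n >= 2")
    if np.std(m) == 0 or np.std(e) == 0:
        raise ValueError("R^2 undefined for a constant sequence")
    r, p_value = _stats.pearsonr(m, e)
    r2 = float(r * r)
    adjusted = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
    return RSquared(r2, float(adjusted), float(p_value))
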