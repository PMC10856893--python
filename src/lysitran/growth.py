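"""Leaf-area index from leaf measurements, and its daily interpolation.

Tomato leaf area is estimated allometrically: single-leaf area is
(leaf length × maximum leaf width) × 0.64, a reduction coefficient that
corrects the bounding rectangle for the compound leaf's outline.  LAI is
total leaf area per plant (m²) divided by the ground area each plant
occupies.  LAI is measured every ~10 days and interpolated to daily
resolution with a shape-preserving piecewise cubic Hermite interpolant
(PCHIP), which passes through every knot and cannot overshoot on monotone
segments — the property that matters when a bounded canopy trajectory is
fed into log-transformed regression terms.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .exceptions import ParameterError
from .water_balance import DEFAULT_PLANT_DENSITY

#: Reduction coefficient from leaf bounding rectangle to true leaf area.
LEAF_AREA_COEFFICIENT = 0.64

#: Ground area per plant (m²), 1 / planting density.
DEFAULT_GROUND_AREA = 1.0 / DEFAULT_PLANT_DENSITY


def leaf_area(length: float, max_width: float) -> float:
    """Single-leaf area (cm²) from length and maximum width (cm)."""
    length = np.asarray(length, dtype=float)
    max_width = np.asarray(max_width, dtype=float)
    if np.any(length < 0) or np.any(max_width < 0):
        raise ParameterError("leaf dimensions must be non-negative")
    out = length * max_width * LEAF_AREA_COEFFICIENT
    return float(out) if out.ndim == 0 else out


def lai_from_plant(
    leaves: Iterable[Tuple[float, float]],
    ground_area_per_plant: float = DEFAULT_GROUND_AREA,
) -> float:
    """Leaf-area index (m²·m⁻²) of one plant.

    ``leaves`` is an iterable of (length cm, max width cm) pairs; areas are
    summed in cm², converted to m² (× 10⁻⁴), and divided by the ground
    area the plant occupies.
    """
    if not np.isfinite(ground_area_per_plant) or ground_area_per_plant <= 0:
        raise ParameterError(
            f"ground_area_per_plant must be > 0, got {ground_area_per_plant}"
        )
    total_cm2 = 0.0
    for length, width in leaves:
        total_cm2 += leaf_area(length, width)
    return total_cm2 * 1e-4 / ground_area_per_plant


def interpolate_daily_lai(measurements: Sequence[Tuple[float, float]]) -> pd.Series:
    """Interpolate sparse (day, LAI) measurements to every integer day.

    Uses a shape-preserving piecewise cubic Hermite interpolant: exact at
    the knots, monotone on monotone data.  Extrapolation beyond the first
    and last measured days is refused — only the interval between
    measurements is defined.

    Parameters
    ----------
    measurements
        Pairs (day, lai) with strictly increasing days; at least two.

    Returns
    -------
    Series indexed by integer day from the first to the last measured day.
    """
    measurements = list(measurements)
    if len(measurements) < 2:
        raise ParameterError("need at least two measurements to interpolate")
    days = np.asarray([m[0] for m in measurements], dtype=float)
    lai = np.asarray([m[1] for m in measurements], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ParameterError("measurement days must be strictly increasing")
    interp = PchipInterpolator(days, lai, extrapolate=False)
    grid = np.arange(int(np.ceil(days[0])), int(np.floor(days[-1])) + 1)
    values = interp(grid)
    return pd.Series(values, index=grid, name="lai")
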