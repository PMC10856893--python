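"""Daily transpiration from weighing-lysimeter records.

A weighed substrate unit (tank + coir substrate + plants) loses mass only
through plant transpiration: the coir strips are wrapped in film so surface
evaporation is negligible, and drainage is captured in a return tank.  With
morning mass W_i, irrigation I_i and return flow R_i (all kg), daily
transpiration per plant unit is the mass balance

    Td_i = W_i + I_i − R_i − W_{i+1}                                  (kg)

and the area-based depth equivalent is

    Tm_i = Td_i × PD                                              (mm·d⁻¹)

where PD is planting density (plants·m⁻²); 1 kg water per m² equals 1 mm.
This module also houses water-use efficiency, the percent-change helper
used for treatment comparisons, and the deficit-irrigation trigger rule
(irrigate when the substrate water store falls below a fixed fraction of
its water-holding capacity).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParameterError

#: Default planting density, plants·m⁻²: wide/narrow row spacing of
#: 1.0 m / 0.4 m (mean row pitch 0.7 m) with 0.3 m in-row plant spacing,
#: i.e. 1 / (0.7 × 0.3).
DEFAULT_PLANT_DENSITY = 1.0 / (0.7 * 0.3)

DayLike = Union[int, np.integer, pd.Timestamp]


@dataclass(frozen=True)
class WeighingRecord:
    """One plant-unit's weighing for one day (all masses kg)."""

    date: DayLike
    w_morning: float
    irrigation: float
    return_flow: float

    def __post_init__(self):
        for name in ("w_morning", "irrigation", "return_flow"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class TranspirationDay:
    """Daily transpiration: per-plant mass (kg) and depth (mm·d⁻¹)."""

    date: DayLike
    td_mass: float
    tm_depth: float
    flag: str = "ok"


def _next_day(date: DayLike):
    if isinstance(date, (int, np.integer)):
        return date + 1
    return pd.Timestamp(date) + pd.Timedelta(days=1)


def daily_transpiration(
    today: WeighingRecord,
    tomorrow: WeighingRecord,
    plant_density: float = DEFAULT_PLANT_DENSITY,
) -> TranspirationDay:
    """Mass-balance transpiration between two consecutive morning weighings.

    Negative balances (condensation or weighing error) are clipped to zero
    and flagged ``negative_clipped``.

    Raises
    ------
    AlignmentError
        If ``tomorrow`` is not the calendar day after ``today``.
    """
    if _next_day(today.date) != (
        pd.Timestamp(tomorrow.date)
        if not isinstance(tomorrow.date, (int, np.integer))
        else tomorrow.date
    ):
        raise AlignmentError(
            f"records are not consecutive days: {today.date!r} then {tomorrow.date!r}"
        )
    td = today.w_morning + today.irrigation - today.return_flow - tomorrow.w_morning
    flag = "ok"
    if td < 0:
        td, flag = 0.0, "negative_clipped"
    return TranspirationDay(
        date=today.date,
        td_mass=td,
        tm_depth=mass_to_depth(td, plant_density),
        flag=flag,
    )


def transpiration_series(
    weighing: pd.DataFrame, plant_density: float = DEFAULT_PLANT_DENSITY
) -> pd.DataFrame:
    """Apply the daily mass balance down a table of consecutive weighings.

    Parameters
    ----------
    weighing
        DataFrame with columns ``date, w_morning, irrigation, return_flow``,
        one row per morning, consecutive days.  The last row supplies only
        the closing mass; n rows yield n−1 transpiration days.

    Returns
    -------
    DataFrame with columns ``date, td_mass, tm_depth, flag``.
    """
    required = {"date", "w_morning", "irrigation", "return_flow"}
    missing = required - set(weighing.columns)
    if missing:
        raise ParameterError(f"weighing table missing columns: {sorted(missing)}")
    if len(weighing) < 2:
        raise ParameterError("need at least two consecutive weighings")
    df = weighing.reset_index(drop=True)
    dates = df["date"].to_numpy()
    if np.issubdtype(np.asarray(dates).dtype, np.integer):
        gaps = np.diff(dates) != 1
    else:
        ts = pd.to_datetime(df["date"])
        gaps = ts.diff().iloc[1:] != pd.Timedelta(days=1)
    if np.any(np.asarray(gaps)):
        raise AlignmentError("weighing dates are not consecutive days")

    w = df["w_morning"].to_numpy(dtype=float)
    irr = df["irrigation"].to_numpy(dtype=float)
    ret = df["return_flow"].to_numpy(dtype=float)
    td = w[:-1] + irr[:-1] - ret[:-1] - w[1:]
    flag = np.where(td < 0, "negative_clipped", "ok")
    td = np.where(td < 0, 0.0, td)
    return pd.DataFrame(
        {
            "date": df["date"].iloc[:-1].to_numpy(),
            "td_mass": td,
            "tm_depth": mass_to_depth(td, plant_density),
            "flag": flag,
        }
    )


def mass_to_depth(td_mass, plant_density: float = DEFAULT_PLANT_DENSITY):
    """Convert per-plant water mass (kg·plant⁻¹) to area depth (mm·d⁻¹).

    tm = td_mass × PD: each plant occupies 1/PD m² of ground, and 1 kg of
    water spread over 1 m² is a 1 mm layer.
    """
    if not np.isfinite(plant_density) or plant_density <= 0:
        raise ParameterError(f"plant_density must be > 0, got {plant_density}")
    td_mass = np.asarray(td_mass, dtype=float)
    out = td_mass * plant_density
    return float(out) if out.ndim == 0 else out


def wue(yield_per_plant: float, water_consumption: float) -> float:
    """Water-use efficiency WUE = Ya / T (kg·m⁻³).

    ``yield_per_plant`` in kg·plant⁻¹, ``water_consumption`` in m³·plant⁻¹.
    """
    if not np.isfinite(water_consumption) or water_consumption <= 0:
        raise ParameterError(
            f"water consumption must be > 0 m³, got {water_consumption}"
        )
    return float(yield_per_plant) / float(water_consumption)


def percent_change(
    reference: float, value: float, denominator: str = "reference"
) -> float:
    """Signed percent change 100 × (value − reference) / denominator.

    ``denominator`` selects the base: ``"reference"`` for the usual
    change-relative-to-control, ``"value"`` for comparisons phrased
    relative to the later figure.  Full precision is returned; round only
    at display.
    """
    if denominator == "reference":
        base = reference
    elif denominator == "value":
        base = value
    else:
        raise ParameterError("denominator must be 'reference' or 'value'")
    if base == 0 or not np.isfinite(base):
        raise ParameterError("chosen denominator is zero or non-finite")
    return 100.0 * (value - reference) / base


TriggerDecision = namedtuple("TriggerDecision", ["decision", "refill"])


def irrigation_trigger(
    store: float, capacity: float, lower_limit_frac: float
) -> TriggerDecision:
    """Deficit-irrigation trigger rule.

    Irrigate iff the substrate water store has fallen strictly below
    ``lower_limit_frac`` of the water-holding capacity; the refill amount
    restores the store to capacity.  The boundary case (store exactly at
    the limit) holds — the strict inequality is a deliberate convention.
    """
    if not np.isfinite(capacity) or capacity <= 0:
        raise ParameterError(f"capacity must be > 0, got {capacity}")
    if not (0 < lower_limit_frac <= 1):
        raise ParameterError(
            f"lower_limit_frac must lie in (0, 1], got {lower_limit_frac}"
        )
    if store < lower_limit_frac * capacity:
        return TriggerDecision("irrigate", capacity - store)
    return TriggerDecision("hold", 0.0)
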