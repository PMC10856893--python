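"""Seeded synthetic greenhouse scenarios.

The raw two-season experiment behind this package is not publicly
deposited, so every downstream stage is exercised on synthetic data with
the same statistical structure:

* **Microclimate** — each driver is lognormal around its stage mean with
  a stationary mean-reverting lag-1 autoregressive anomaly process, so
  values are strictly positive and right-skewed like real daily weather
  and the configured mean is reproduced exactly in expectation.  VPD and
  Ta anomalies respond positively to the day's radiation anomaly (sunny
  days are warmer and drier) with independent AR(1) noise on top; wind is
  independent.  Temperature varies proportionally less than radiation
  (thermal inertia of the greenhouse); see ``DRIVER_CV_SCALE``.  Stage
  means default to the study's printed per-stage climatology (see
  :mod:`lysitran.datasets`).
* **Canopy** — the LAI truth curve is logistic: sigmoid rise through
  flowering/fruit-setting to a plateau ``lai_max``, sampled on the
  ~10-day measurement schedule with optional measurement noise.
* **Transpiration** — the segmented flowering/picking model evaluated on
  the generated drivers, plus Gaussian observation noise; negative draws
  are floored at zero and flagged.
* **Weighing records** — a daily substrate water store driven by the
  transpiration series and the deficit-irrigation trigger rule.  All
  masses (and the encoded transpiration) are quantised to a 2⁻¹⁰ kg
  binary grid — about 1 g, the resolution of the weighing scale — which
  makes every mass-balance sum exact in double precision, so extracting
  transpiration from the records recovers the encoded series bit for bit.

All draws flow from explicit integer seeds; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParameterError
from .transpiration import ModelCoefficients, evaluate
from .water_balance import irrigation_trigger

#: Mass quantum, kg.  2⁻¹⁰ kg ≈ 0.98 g matches the scale's 1 g accuracy;
#: being a power of two it keeps all mass sums exact in IEEE doubles.
MASS_QUANTUM = 2.0**-10

#: Default fractional day-to-day variability and persistence of drivers,
#: and the DAR→(VPD, Ta) coupling strength.  The study reports stage
#: means only; these are realistic choices for daily greenhouse weather
#: (overcast days commonly halve radiation; conditions persist on synoptic
#: time scales of a few days).
DEFAULT_CV = 0.35
DEFAULT_AR1 = 0.5
DEFAULT_COUPLING = 0.6

#: Per-driver multiplier on the configured cv: radiation and VPD carry the
#: full day-to-day variability, daily-mean air temperature much less (the
#: glasshouse buffers it), wind somewhat less.
DRIVER_CV_SCALE = {"dar": 1.0, "vpd": 1.0, "ta": 0.3, "w": 0.8}


@dataclass(frozen=True)
class StageParams:
    """Microclimate generator settings for one growth stage."""

    stage_name: str
    n_days: int
    mean_dar: float
    mean_vpd: float
    mean_ta: float
    mean_w: float
    cv: float = DEFAULT_CV
    ar1: float = DEFAULT_AR1
    coupling: float = DEFAULT_COUPLING
    seed: int = 0

    def __post_init__(self):
        if self.stage_name not in ("flowering_fruit_setting", "picking"):
            raise ParameterError(f"unknown stage {self.stage_name!r}")
        for name in ("mean_dar", "mean_vpd", "mean_ta", "mean_w"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if not (0 <= self.ar1 < 1):
            raise ParameterError(f"ar1 must lie in [0, 1), got {self.ar1}")
        if self.cv < 0 or not np.isfinite(self.cv):
            raise ParameterError(f"cv must be >= 0, got {self.cv}")
        if self.n_days < 1:
            raise ParameterError(f"n_days must be >= 1, got {self.n_days}")


@dataclass(frozen=True)
class LaiTrajectoryParams:
    """Logistic LAI truth curve and its measurement schedule."""

    lai_max: float = 2.64
    midpoint_day: float = 46.0
    rate: float = 0.115
    measurement_noise_sd: float = 0.0
    measurement_days: Sequence[int] = (30, 40, 50, 60, 70, 80)
    seed: int = 0

    def __post_init__(self):
        if self.lai_max <= 0 or self.rate <= 0:
            raise ParameterError("lai_max and rate must be > 0")
        days = list(self.measurement_days)
        if len(days) == 0:
            raise ParameterError("measurement_days must not be empty")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError("measurement_days must be strictly increasing")


def _ar1_series(n: int, ar1: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) innovations."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    scale = np.sqrt(1.0 - ar1**2)
    eps = rng.standard_normal(n) * scale
    for i in range(1, n):
        z[i] = ar1 * z[i - 1] + eps[i]
    return z


def generate_microclimate(params: StageParams) -> pd.DataFrame:
    """Generate one stage's daily microclimate series.

    Returns DataFrame with columns ``day, dar, ta, vpd, w`` (day is
    0-based within the stage).  Each driver is mean·exp(s·z − s²/2) with
    z its stationary AR(1) anomaly and s = sqrt(ln(1 + cv²)) chosen so
    the arithmetic mean and coefficient of variation equal the configured
    values exactly; values are therefore strictly positive without
    clipping.  Identical parameters and seed reproduce the series
    exactly.
    """
    rng = np.random.default_rng(params.seed)
    n, rho = params.n_days, params.coupling
    z_dar = _ar1_series(n, params.ar1, rng)
    z_vpd = rho * z_dar + np.sqrt(1 - rho**2) * _ar1_series(n, params.ar1, rng)
    z_ta = rho * z_dar + np.sqrt(1 - rho**2) * _ar1_series(n, params.ar1, rng)
    z_w = _ar1_series(n, params.ar1, rng)

    def realise(mean, z, scale):
        cv = params.cv * scale
        s = np.sqrt(np.log1p(cv**2))
        return mean * np.exp(s * z - 0.5 * s**2)

    return pd.DataFrame(
        {
            "day": np.arange(n),
            "dar": realise(params.mean_dar, z_dar, DRIVER_CV_SCALE["dar"]),
            "ta": realise(params.mean_ta, z_ta, DRIVER_CV_SCALE["ta"]),
            "vpd": realise(params.mean_vpd, z_vpd, DRIVER_CV_SCALE["vpd"]),
            "w": realise(params.mean_w, z_w, DRIVER_CV_SCALE["w"]),
        }
    )


def logistic_lai(day, params: LaiTrajectoryParams):
    """Noiseless logistic LAI truth curve evaluated at ``day``."""
    day = np.asarray(day, dtype=float)
    out = params.lai_max / (1.0 + np.exp(-params.rate * (day - params.midpoint_day)))
    return float(out) if out.ndim == 0 else out


def generate_lai_trajectory(params: LaiTrajectoryParams) -> pd.DataFrame:
    """Sample the LAI curve on the measurement schedule.

    Returns DataFrame with columns ``day, lai``.  Measurement noise is
    Gaussian with sd ``measurement_noise_sd``; noisy values are floored
    at a small positive LAI.
    """
    days = np.asarray(list(params.measurement_days), dtype=int)
    lai = logistic_lai(days, params)
    if params.measurement_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        lai = lai + rng.normal(0.0, params.measurement_noise_sd, len(days))
        lai = np.maximum(lai, 1e-3)
    return pd.DataFrame({"day": days, "lai": lai})


def generate_transpiration(
    microclimate: pd.DataFrame,
    lai,
    coefs: ModelCoefficients,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """True-model transpiration plus observation noise.

    Evaluates the model form of ``coefs`` on the drivers (``lai`` is a
    daily series aligned with ``microclimate``; ignored by forms that do
    not use it) and adds Normal(0, noise_sd²) noise.  Negative draws are
    floored at 0 and flagged.  Returns DataFrame ``day, tm, flag``.
    """
    lai = np.asarray(lai, dtype=float)
    if len(lai) != len(microclimate):
        raise AlignmentError(
            f"lai series length {len(lai)} != microclimate length {len(microclimate)}"
        )
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    drivers = microclimate.copy()
    drivers["lai"] = lai
    tm = evaluate(coefs.form, drivers, coefs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tm = tm + rng.normal(0.0, noise_sd, len(tm))
    flag = np.where(tm < 0, "negative_clipped", "ok")
    tm = np.where(tm < 0, 0.0, tm)
    return pd.DataFrame({"day": microclimate["day"].to_numpy(), "tm": tm, "flag": flag})


@dataclass(frozen=True)
class IrrigationPolicy:
    """Deficit-irrigation trigger configuration.

    ``lower_limit_frac`` is the fraction of water-holding capacity below
    which irrigation fires (0.80/0.70/0.60 for the wettest/middle/driest
    treatments); ``drain_fraction`` is the extra water applied on each
    event that drains straight to the return tank, so records carry a
    realistic nonzero return flow.
    """

    lower_limit_frac: float = 0.70
    drain_fraction: float = 0.10

    def __post_init__(self):
        if not (0 < self.lower_limit_frac <= 1):
            raise ParameterError("lower_limit_frac must lie in (0, 1]")
        if self.drain_fraction < 0:
            raise ParameterError("drain_fraction must be >= 0")


def _quantise(x):
    """Snap mass values (kg) to the binary gram-scale grid."""
    return np.round(np.asarray(x, dtype=float) / MASS_QUANTUM) * MASS_QUANTUM


def generate_weighing_records(
    tm: Sequence[float],
    irrigation_policy: IrrigationPolicy = IrrigationPolicy(),
    capacity: float = 4.0,
    tare: float = 30.0,
) -> pd.DataFrame:
    """Weighing records that encode a per-plant transpiration series.

    Parameters
    ----------
    tm
        Daily transpiration per plant unit, kg·plant⁻¹ (non-negative).
    irrigation_policy, capacity, tare
        Trigger rule, substrate water-holding capacity (kg) and the fixed
        mass of tank + dry substrate + plant (kg).

    Returns
    -------
    DataFrame with n+1 rows and columns
    ``day, w_morning, irrigation, return_flow, td_encoded`` — morning
    masses bracket each transpiration day; the final row closes the series
    (irrigation, return flow and ``td_encoded`` zero).  ``td_encoded`` is
    the gram-quantised transpiration actually written into the masses; the
    water-balance extraction recovers it exactly, and the substrate store
    never exceeds capacity nor goes negative.
    """
    if not np.isfinite(capacity) or capacity <= 0:
        raise ParameterError(f"capacity must be > 0, got {capacity}")
    tm = np.asarray(tm, dtype=float)
    if np.any(tm < 0) or not np.all(np.isfinite(tm)):
        raise ParameterError("tm must be finite and non-negative")
    if np.any(tm > capacity):
        raise ParameterError("daily transpiration cannot exceed the water store")
    td = _quantise(tm)
    capacity = float(_quantise(capacity))
    tare = float(_quantise(tare))
    drain = irrigation_policy.drain_fraction
    frac = irrigation_policy.lower_limit_frac

    n = len(td)
    store = capacity
    rows = []
    for i in range(n):
        w_morning = tare + store
        decision = irrigation_trigger(store, capacity, frac)
        # also refill if today's demand would drive the store negative
        if decision.decision == "irrigate" or store - td[i] < 0:
            refill = capacity - store
            irrigation = float(_quantise(refill * (1.0 + drain)))
            return_flow = irrigation - refill  # exact on the binary grid
        else:
            irrigation, return_flow = 0.0, 0.0
        store = store + irrigation - return_flow - td[i]
        rows.append((i, w_morning, irrigation, return_flow, td[i]))
    rows.append((n, tare + store, 0.0, 0.0, 0.0))
    return pd.DataFrame(
        rows, columns=["day", "w_morning", "irrigation", "return_flow", "td_encoded"]
    )


# ---------------------------------------------------------------------------
# whole-scenario convenience

@dataclass(frozen=True)
class ScenarioConfig:
    """One-stage synthetic scenario: drivers + canopy + transpiration + weighing."""

    stage: StageParams
    lai: LaiTrajectoryParams = field(default_factory=LaiTrajectoryParams)
    coefs: Optional[ModelCoefficients] = None
    noise_sd: float = 0.05
    plant_density: float = 1.0 / (0.7 * 0.3)
    policy: IrrigationPolicy = field(default_factory=IrrigationPolicy)
    capacity: float = 4.0


def generate_scenario(config: ScenarioConfig) -> dict:
    """Generate a coherent scenario; returns a dict of DataFrames.

    Keys: ``microclimate``, ``growth`` (measured LAI), ``lai_daily``
    (daily truth curve over the stage), ``transpiration`` (mm·d⁻¹ truth +
    noise), ``weighing`` (records encoding the per-plant mass series).
    Daily LAI is the noiseless truth curve evaluated from the day the
    canopy reaches LAI = 1 (the flowering branch's domain) onwards.
    """
    from .transpiration import PUBLISHED

    stage = config.stage
    coefs = config.coefs or PUBLISHED[
        "flowering" if stage.stage_name == "flowering_fruit_setting" else "picking"
    ]
    climate = generate_microclimate(stage)
    growth = generate_lai_trajectory(config.lai)
    # first day with LAI >= 1 on the truth curve (logistic crossing)
    crossing = config.lai.midpoint_day - np.log(config.lai.lai_max - 1.0) / config.lai.rate
    day0 = int(np.ceil(max(config.lai.measurement_days[0], crossing)))
    lai_daily = logistic_lai(day0 + climate["day"].to_numpy(), config.lai)
    transp = generate_transpiration(
        climate, lai_daily, coefs, config.noise_sd, seed=stage.seed + 1
    )
    td_kg = transp["tm"].to_numpy() / config.plant_density
    weighing = generate_weighing_records(
        td_kg, config.policy, capacity=config.capacity
    )
    return {
        "microclimate": climate,
        "growth": growth,
        "lai_daily": pd.DataFrame({"day": climate["day"], "lai": lai_daily}),
        "transpiration": transp,
        "weighing": weighing,
    }
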