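"""Daily driver variables from raw greenhouse sensor readings.

The transpiration models are driven by four daily quantities:

* ``dar`` — daily accumulated solar radiation expressed as a
  water-equivalent depth (mm·d⁻¹): integrated shortwave energy divided by
  the latent heat of vaporisation.
* ``ta`` — daily mean air temperature (°C).
* ``vpd`` — daily mean vapor-pressure deficit (kPa), the drying power of
  the greenhouse air.
* ``w`` — daily mean wind speed (m·s⁻¹).

Raw logger files hold one row per averaging interval (typically 30 min)
with columns ``timestamp, rs, ta, rh, w`` where ``rs`` is the shortwave
flux expressed as an equivalent daily rate (MJ·m⁻²·d⁻¹).  VPD is computed
per reading and then averaged: averaging temperature and humidity first
and converting once would bias the mean because saturation vapor pressure
is convex in temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParameterError

#: Latent heat of vaporisation, MJ·kg⁻¹ (FAO-56 convention, taken constant).
LAMBDA_MJ_PER_KG = 2.45

#: Minimum fraction of expected readings for a day to be considered complete.
COVERAGE_THRESHOLD = 0.80


def saturation_vapor_pressure(ta):
    """Saturation vapor pressure e_s(Ta) in kPa (Tetens/Magnus form).

    e_s = 0.6108 · exp(17.27 · Ta / (Ta + 237.3)) with Ta in °C.
    """
    ta = np.asarray(ta, dtype=float)
    return 0.6108 * np.exp(17.27 * ta / (ta + 237.3))


def vpd_from_ta_rh(ta, rh):
    """Vapor-pressure deficit (kPa) from air temperature (°C) and RH (%).

    VPD = e_s(Ta) · (1 − RH/100).  Scalar in, scalar out; arrays broadcast.

    Raises
    ------
    ParameterError
        If any RH value lies outside [0, 100].
    """
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100) or not np.all(np.isfinite(rh)):
        raise ParameterError("relative humidity must lie in [0, 100] %")
    out = saturation_vapor_pressure(ta) * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


def radiation_to_dar(rs):
    """Convert solar radiation (MJ·m⁻²·d⁻¹) to water-equivalent depth (mm·d⁻¹).

    dar = rs / λ with λ = 2.45 MJ·kg⁻¹; 1 kg of water per m² is 1 mm depth.
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(rs < 0) or not np.all(np.isfinite(rs)):
        raise ParameterError("radiation must be finite and non-negative")
    out = rs / LAMBDA_MJ_PER_KG
    return float(out) if out.ndim == 0 else out


def aggregate_daily(readings: pd.DataFrame, expected_per_day: int = 48) -> pd.DataFrame:
    """Aggregate timestamped sensor readings to one row per calendar day.

    Parameters
    ----------
    readings
        DataFrame with columns ``timestamp`` (parseable datetimes), ``rs``
        (MJ·m⁻²·d⁻¹ equivalent rate), ``ta`` (°C), ``rh`` (%), ``w`` (m·s⁻¹).
    expected_per_day
        Number of readings a complete day should contain (48 for 30-min
        logging).  Days below ``COVERAGE_THRESHOLD`` of this are emitted
        but flagged ``low_coverage``.

    Returns
    -------
    DataFrame with columns ``date, dar, ta, vpd, w, n_readings, flag``
    sorted by date.  ``dar`` is the time-integrated radiation converted to
    mm·d⁻¹ (the mean rate over the day's readings divided by λ); ``vpd``
    is the mean of per-reading VPD values.
    """
    required = {"timestamp", "rs", "ta", "rh", "w"}
    missing = required - set(readings.columns)
    if missing:
        raise ParameterError(f"readings missing columns: {sorted(missing)}")
    if readings.empty:
        return pd.DataFrame(
            columns=["date", "dar", "ta", "vpd", "w", "n_readings", "flag"]
        )
    df = readings.copy()
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ParameterError(f"unparseable timestamps: {exc}") from None
    df["vpd"] = vpd_from_ta_rh(df["ta"].to_numpy(), df["rh"].to_numpy())
    df["date"] = df["timestamp"].dt.normalize()

    grouped = df.groupby("date", sort=True)
    out = grouped.agg(
        rs_mean=("rs", "mean"),
        ta=("ta", "mean"),
        vpd=("vpd", "mean"),
        w=("w", "mean"),
        n_readings=("rs", "size"),
    ).reset_index()
    out["dar"] = radiation_to_dar(out.pop("rs_mean").to_numpy())
    out["flag"] = np.where(
        out["n_readings"] >= COVERAGE_THRESHOLD * expected_per_day, "ok", "low_coverage"
    )
    return out[["date", "dar", "ta", "vpd", "w", "n_readings", "flag"]]
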