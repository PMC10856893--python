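"""Packaged reference tables from the two-season greenhouse experiment.

Three small CSVs ship with the package: treatment-level yield, water-use
efficiency and fruit-quality indicators for both seasons; the measured
LAI trajectories per treatment; and the per-stage microclimate
climatology (means of DAR, VPD, Ta, W).  They power the treatment
comparisons, the TOPSIS ranking, and the synthetic generator's default
study conditions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exceptions import ParameterError
from .synthetic import StageParams

#: TOPSIS indicator columns, all benefit criteria (organic acidity is
#: deliberately not part of the decision matrix).
DECISION_CRITERIA = ["yield_per_plant", "wue", "tss", "vc", "sar"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("lysitran.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_yield_quality() -> pd.DataFrame:
    """Yield, WUE and quality indicators per year × treatment."""
    return _read("yield_quality.csv")


def load_decision_matrix(year: int) -> pd.DataFrame:
    """Treatments × benefit indicators for TOPSIS, one season."""
    df = load_yield_quality()
    df = df.loc[df["year"] == year]
    if df.empty:
        raise ParameterError(f"no indicator data for year {year}")
    return df.set_index("treatment")[DECISION_CRITERIA]


def load_lai_trajectory(year: int, treatment: str) -> pd.DataFrame:
    """Measured (day, lai) trajectory of one treatment in one season."""
    df = _read("lai_trajectories.csv")
    out = df.loc[(df["year"] == year) & (df["treatment"] == treatment), ["day", "lai"]]
    if out.empty:
        raise ParameterError(f"no LAI trajectory for {year} {treatment!r}")
    return out.reset_index(drop=True)


def load_stage_climate() -> pd.DataFrame:
    """Per-stage microclimate means for both seasons."""
    return _read("stage_climate.csv")


def stage_params(year: int, stage: str, seed: int = 0, **overrides) -> StageParams:
    """Build generator :class:`StageParams` from the packaged climatology."""
    df = load_stage_climate()
    row = df.loc[(df["year"] == year) & (df["stage"] == stage)]
    if row.empty:
        raise ParameterError(f"no climatology for {year} {stage!r}")
    row = row.iloc[0]
    kwargs = dict(
        stage_name=stage,
        n_days=int(row["n_days"]),
        mean_dar=float(row["mean_dar"]),
        mean_vpd=float(row["mean_vpd"]),
        mean_ta=float(row["mean_ta"]),
        mean_w=float(row["mean_w"]),
        seed=seed,
    )
    kwargs.update(overrides)
    return StageParams(**kwargs)
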