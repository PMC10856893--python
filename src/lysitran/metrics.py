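"""Model-evaluation statistics.

With T the simulated and M the measured daily transpiration series:

    MAE  = mean |T − M|                                       (mm·d⁻¹)
    RMSE = sqrt(mean (T − M)²)                                (mm·d⁻¹)
    MRE  = 100 · mean(|T − M| / M)                            (%)
    NSE  = 1 − Σ(T − M)² / Σ(M − M̄)²                          (−)
    R²   — coefficient of determination of the simulated-vs-measured
           ordinary least-squares line.

MRE uses absolute relative errors and NSE the squared sums (the standard
definitions; anything else is dimensionally inconsistent and incompatible
with NSE values in (0, 1]).  MRE is undefined whenever a measured value
is zero and is then reported missing with a flag; NSE is undefined for a
constant measured series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation statistics for one model on one series."""

    n: int
    mae: float
    rmse: float
    mre: float  # percent; NaN if any measured value is zero
    nse: float
    r2: float
    flag: str = "ok"

    def to_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "mre": self.mre,
            "nse": self.nse,
            "r2": self.r2,
            "flag": self.flag,
        }


def compute_metrics(simulated, measured) -> MetricsReport:
    """Compute MAE, RMSE, MRE, NSE and R² of simulated against measured."""
    t = np.asarray(simulated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ParameterError("simulated and measured must be 1-D and equal length")
    n = len(t)
    if n < 2:
        raise ParameterError("need at least 2 paired observations")
    err = t - m
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    denom = float(np.sum((m - m.mean()) ** 2))
    if denom == 0:
        raise ParameterError("measured series is constant; NSE is undefined")
    nse = 1.0 - float(np.sum(err**2)) / denom
    flag = "ok"
    if np.any(m == 0):
        mre, flag = np.nan, "mre_undefined"
    else:
        mre = 100.0 * float(np.mean(np.abs(err) / np.abs(m)))
    r2 = float(stats.linregress(m, t).rvalue ** 2)
    return MetricsReport(n=n, mae=mae, rmse=rmse, mre=mre, nse=nse, r2=r2, flag=flag)


#: Direction of "better" per metric column.
_LOWER_BETTER = {"mae": True, "rmse": True, "mre": True, "nse": False, "r2": False}


def compare_models(reports: Dict[Tuple[str, str], MetricsReport]) -> pd.DataFrame:
    """Tabulate metric reports keyed by (stage, model); mark best per column.

    Returns a DataFrame indexed by (stage, model) with the metric columns
    and parallel boolean ``best_*`` columns marking, within each stage,
    the model with the best value of that metric.
    """
    if not reports:
        raise ParameterError("no reports to compare")
    rows = {key: rep.to_dict() for key, rep in reports.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["stage", "model"])
    for col, lower in _LOWER_BETTER.items():
        best = (
            table.groupby(level="stage")[col].transform("min" if lower else "max")
        )
        table[f"best_{col}"] = table[col] == best
    return table
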