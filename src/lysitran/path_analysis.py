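"""Predictor screening: correlations and path analysis.

Path analysis decomposes each driver's Pearson correlation with daily
transpiration into a *direct* effect — its standardized partial
regression coefficient P_i, obtained by solving R_xx · P = r_xy where
R_xx is the predictor correlation matrix and r_xy the predictor–response
correlations — and *indirect* effects routed through the other,
correlated drivers, indirect(i→via j) = r_ij · P_j.  For full-rank
predictors the decomposition is exact:

    r_i = P_i + Σ_{j≠i} r_ij · P_j

which doubles as a numerical self-check.  Standardization uses the
sample (n−1) standard deviation.  Significance stars follow the common
agronomy convention (* p<0.05, ** p<0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MulticollinearityError, ParameterError


def pearson_with_response(X: pd.DataFrame, y) -> pd.DataFrame:
    """Pearson r and two-sided p-value of each predictor against y.

    Constant columns get r = NaN and flag ``constant``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ParameterError("need at least 3 observations")
    if len(y) != len(X):
        raise ParameterError("X and y lengths differ")
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x, ddof=1) == 0:
            rows.append((col, np.nan, np.nan, "constant"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((col, r, p, "ok"))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "flag"]).set_index(
        "variable"
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PathResults:
    """Direct/indirect decomposition of driver–transpiration correlations."""

    variables: List[str]
    direct: pd.Series
    indirect: pd.DataFrame  # entry (i, j): effect of i routed via j; diag 0
    correlation: pd.Series
    p_values: pd.Series

    @property
    def indirect_sum(self) -> pd.Series:
        return self.indirect.sum(axis=1).rename("indirect_sum")

    def decomposition_residual(self) -> pd.Series:
        """r − (direct + Σ indirect); ~0 for full-rank inputs."""
        return self.correlation - (self.direct + self.indirect_sum)

    def rank_drivers(self) -> List[str]:
        """Variables ordered by |r| descending; ties alphabetical (flagged)."""
        absr = self.correlation.abs()
        order = sorted(self.variables, key=lambda v: (-absr[v], v))
        ties = absr.duplicated(keep=False)
        if ties.any():
            tied = sorted(absr.index[ties])
            order = [f"{v} (tied)" if v in tied else v for v in order]
        return order

    def to_frame(self) -> pd.DataFrame:
        out = self.indirect.copy()
        out.insert(0, "direct", self.direct)
        out["indirect_sum"] = self.indirect_sum
        out["r"] = self.correlation
        out["p"] = self.p_values
        out["sig"] = [_stars(p) for p in self.p_values]
        return out

    def summary(self) -> str:
        frame = self.to_frame()
        lines = ["Path analysis of daily transpiration drivers", "=" * 60]
        lines.append(frame.round(3).to_string())
        lines.append("-" * 60)
        lines.append("ranking by |r|: " + " > ".join(self.rank_drivers()))
        return "\n".join(lines)


class PathAnalysis:
    """Correlation + path analysis of a driver table against a response.

    Parameters
    ----------
    y
        Response series (daily transpiration, mm·d⁻¹).
    X
        Predictor DataFrame (drivers), n rows > number of columns.
    """

    def __init__(self, y, X: pd.DataFrame):
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ParameterError("X and y lengths differ")
        if len(y) <= X.shape[1]:
            raise ParameterError("need more observations than predictors")
        self.y = y
        self.X = X

    def fit(self) -> PathResults:
        cols = list(self.X.columns)
        pear = pearson_with_response(self.X, self.y)
        if (pear["flag"] == "constant").any():
            bad = list(pear.index[pear["flag"] == "constant"])
            raise MulticollinearityError(f"constant predictor columns: {bad}")
        r_xy = pear["r"].to_numpy()
        R_xx = np.atleast_2d(np.corrcoef(self.X.to_numpy(dtype=float), rowvar=False))
        cond = np.linalg.cond(R_xx)
        if not np.isfinite(cond) or cond > 1e10:
            # name the most collinear pair for the error message
            off = np.abs(R_xx - np.eye(len(cols)))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise MulticollinearityError(
                f"predictor correlation matrix is singular "
                f"(worst pair: {cols[i]} / {cols[j]}, |r| = {off[i, j]:.4f})"
            )
        direct = np.linalg.solve(R_xx, r_xy)
        indirect = R_xx * direct[np.newaxis, :]  # (i, j) = r_ij * P_j
        np.fill_diagonal(indirect, 0.0)
        return PathResults(
            variables=cols,
            direct=pd.Series(direct, index=cols, name="direct"),
            indirect=pd.DataFrame(indirect, index=cols, columns=cols),
            correlation=pear["r"].rename("r"),
            p_values=pear["p"].rename("p"),
        )


def path_analysis(X: pd.DataFrame, y) -> PathResults:
    """Functional wrapper around :class:`PathAnalysis`."""
    return PathAnalysis(y, X).fit()


def rank_drivers(result: PathResults) -> List[str]:
    """Variables ranked strong-to-weak by |correlation| with the response."""
    return result.rank_drivers()
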