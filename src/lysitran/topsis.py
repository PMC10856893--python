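"""TOPSIS ranking of irrigation treatments.

TOPSIS (Technique for Order Preference by Similarity to Ideal Solution)
ranks alternatives by their relative closeness to an ideal point in
weighted, normalized criterion space.  For a decision matrix of
treatments × indicators (here: yield per plant, WUE, total soluble
solids, vitamin C, sugar–acid ratio — all benefit criteria):

1. normalize each column (vector norm by default);
2. weight columns (equal weights by default; Shannon-entropy weights
   available);
3. ideal = per-criterion best, anti-ideal = per-criterion worst;
4. D± = Euclidean distances to ideal/anti-ideal;
5. closeness Ci = D⁻ / (D⁺ + D⁻), ranked descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError


def _validate_matrix(matrix: pd.DataFrame):
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ParameterError("decision matrix must be non-empty")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ParameterError("decision matrix entries must be finite and > 0")
    return values


def normalize(
    matrix: pd.DataFrame,
    method: str = "vector",
    directions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Normalize a decision matrix column-wise.

    ``vector``: divide each column by its Euclidean norm (direction
    handled later at the ideal-point step).  ``minmax``: (x−min)/(max−min)
    with cost criteria inverted so every normalized column is benefit.
    """
    values = _validate_matrix(matrix)
    directions = list(directions) if directions is not None else ["benefit"] * matrix.shape[1]
    if len(directions) != matrix.shape[1]:
        raise ParameterError("one direction per criterion required")
    if method == "vector":
        norms = np.sqrt((values**2).sum(axis=0))
        if np.any(norms == 0):
            raise ParameterError("zero column norm in decision matrix")
        out = values / norms
    elif method == "minmax":
        lo, hi = values.min(axis=0), values.max(axis=0)
        if np.any(hi == lo):
            raise ParameterError("constant column under minmax normalization")
        out = (values - lo) / (hi - lo)
        for j, d in enumerate(directions):
            if d == "cost":
                out[:, j] = 1.0 - out[:, j]
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def entropy_weights(normalized: pd.DataFrame) -> pd.Series:
    """Shannon-entropy criterion weights from a normalized matrix.

    Columns that discriminate more between alternatives (lower entropy of
    the column's share distribution) receive larger weights.  A matrix
    whose columns are all non-discriminating degenerates to uniform
    weights.
    """
    values = normalized.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ParameterError("normalized values must be >= 0")
    m = values.shape[0]
    col_sums = values.sum(axis=0)
    if np.any(col_sums == 0):
        raise ParameterError("zero column sum in normalized matrix")
    p = values / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=0) / np.log(m) if m > 1 else np.ones(values.shape[1])
    divergence = 1.0 - entropy
    total = divergence.sum()
    if total <= 1e-12:
        weights = np.full(values.shape[1], 1.0 / values.shape[1])
    else:
        weights = divergence / total
    return pd.Series(weights, index=normalized.columns, name="weight")


@dataclass
class TopsisResult:
    """Distances, closeness and ranks for each alternative."""

    d_plus: pd.Series
    d_minus: pd.Series
    ci: pd.Series
    rank: pd.Series  # 1 = best; ties share the minimum rank
    tied: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "ci": self.ci,
                "rank": self.rank,
            }
        )

    def summary(self) -> str:
        lines = ["TOPSIS ranking", "=" * 40, self.to_frame().round(4).to_string()]
        if self.tied:
            lines.append("note: tied closeness values share the minimum rank")
        return "\n".join(lines)


def topsis(
    matrix: pd.DataFrame,
    weights: Optional[Sequence[float]] = None,
    directions: Optional[Sequence[str]] = None,
    normalization: str = "vector",
) -> TopsisResult:
    """Rank alternatives (rows) over criteria (columns).

    Parameters
    ----------
    matrix
        Alternatives × criteria, strictly positive values.
    weights
        Per-criterion weights, non-negative, summing to 1.  Default equal.
    directions
        ``"benefit"`` (higher better, default) or ``"cost"`` per column.
    normalization
        ``"vector"`` (default) or ``"minmax"``.
    """
    _validate_matrix(matrix)
    if matrix.shape[0] < 2:
        raise ParameterError("need at least two alternatives to rank")
    n_crit = matrix.shape[1]
    directions = list(directions) if directions is not None else ["benefit"] * n_crit
    if weights is None:
        w = np.full(n_crit, 1.0 / n_crit)
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != n_crit or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("weights must be non-negative and sum to 1")
    norm = normalize(matrix, method=normalization, directions=directions)
    v = norm.to_numpy() * w
    if normalization == "minmax":
        # cost criteria already inverted to benefit
        ideal, anti = v.max(axis=0), v.min(axis=0)
    else:
        ideal = np.where(
            [d == "benefit" for d in directions], v.max(axis=0), v.min(axis=0)
        )
        anti = np.where(
            [d == "benefit" for d in directions], v.min(axis=0), v.max(axis=0)
        )
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    total = d_plus + d_minus
    if np.any(total == 0):
        raise ParameterError(
            "degenerate decision matrix: an alternative coincides with both "
            "ideal and anti-ideal (all alternatives identical?)"
        )
    ci = pd.Series(d_minus / total, index=matrix.index, name="ci")
    rank = ci.rank(ascending=False, method="min").astype(int)
    return TopsisResult(
        d_plus=pd.Series(d_plus, index=matrix.index, name="d_plus"),
        d_minus=pd.Series(d_minus, index=matrix.index, name="d_minus"),
        ci=ci,
        rank=rank,
        tied=bool(ci.duplicated().any()),
    )


def rank_report(result: TopsisResult) -> pd.DataFrame:
    """Table with D+, D−, Ci and Rank per alternative."""
    return result.to_frame()
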