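"""Segmented multivariate daily-transpiration models.

Daily transpiration of substrate-grown greenhouse tomato responds to a
different mix of drivers in each growth stage, so the model is segmented:

flowering / fruit-setting (canopy still expanding, LAI < LAI_max)::

    Ts = a·DAR^b + c·ln(VPD) + d·ln(Ta) + e·ln(LAI)

picking (canopy plateaued at LAI_max; LAI drops out, wind enters)::

    Ts = a·DAR^b + c·exp(VPD) + d·ln(Ta) + e·ln(W) + f

and an unsegmented whole-season comparison model::

    T' = β₁·ln(DAR) + β₂·ln(VPD) + β₃·ln(Ta) + β₄·ln(W) + β₅·exp(LAI) + β₆

with DAR the daily accumulated solar radiation (mm·d⁻¹ water equivalent),
VPD the daily mean vapor-pressure deficit (kPa), Ta daily mean air
temperature (°C), W daily mean wind speed (m·s⁻¹) and LAI the leaf-area
index.  Coefficients are estimated by damped (Levenberg–Marquardt) least
squares from a small multi-start grid over the power-law exponent, with
the remaining, conditionally linear coefficients profiled out at each
start.  The unsegmented form is linear after transforming the drivers and
is solved in closed form.

Published coefficient sets ship as defaults in :data:`PUBLISHED`.  Note a
plausibility caveat on the published picking-stage set: evaluated at its
own stage-mean drivers it returns a large negative value (the ln W term
and intercept dominate at greenhouse wind speeds near zero), suggesting a
transcription or unit issue in the source; the functional form stands, and
any quantitative use of this package should refit coefficients to data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    DomainError,
    FitError,
    MulticollinearityError,
    ParameterError,
)

# ---------------------------------------------------------------------------
# coefficient containers

COEF_NAMES: Dict[str, tuple] = {
    "flowering": ("a", "b", "c", "d", "e"),
    "picking": ("a", "b", "c", "d", "e", "f"),
    "unsegmented": ("b_dar", "b_vpd", "b_ta", "b_w", "b_lai", "intercept"),
}

#: Bounds on the power-law exponent b during fitting.
B_BOUNDS = (0.2, 3.0)

#: Floors applied (with a flag) before log transforms; greenhouse wind
#: speed in particular sits near zero and ln 0 is undefined.
LAI_FLOOR = 0.01
W_FLOOR = 0.01


@dataclass(frozen=True)
class ModelCoefficients:
    """Named coefficient vector for one model form."""

    form: str
    values: Mapping[str, float]

    def __post_init__(self):
        if self.form not in COEF_NAMES:
            raise ParameterError(f"unknown model form {self.form!r}")
        names = COEF_NAMES[self.form]
        missing = set(names) - set(self.values)
        if missing:
            raise ParameterError(f"{self.form} coefficients missing {sorted(missing)}")
        vals = np.asarray([self.values[n] for n in names], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ParameterError("coefficients must all be finite")
        object.__setattr__(self, "values", dict(zip(names, (float(v) for v in vals))))

    def as_array(self) -> np.ndarray:
        return np.asarray([self.values[n] for n in COEF_NAMES[self.form]], dtype=float)

    @classmethod
    def from_array(cls, form: str, arr) -> "ModelCoefficients":
        return cls(form, dict(zip(COEF_NAMES[form], np.asarray(arr, dtype=float))))


#: Published coefficient sets (see module docstring for the picking caveat).
PUBLISHED: Dict[str, ModelCoefficients] = {
    "flowering": ModelCoefficients(
        "flowering", {"a": 0.001, "b": 1.261, "c": 0.689, "d": 0.399, "e": 0.527}
    ),
    "picking": ModelCoefficients(
        "picking",
        {"a": 0.011, "b": 1.04, "c": 0.189, "d": -0.110, "e": 5.625, "f": -6.01},
    ),
    "unsegmented": ModelCoefficients(
        "unsegmented",
        {
            "b_dar": 0.514,
            "b_vpd": 0.08,
            "b_ta": 0.379,
            "b_w": 1.05,
            "b_lai": 0.006,
            "intercept": 0.249,
        },
    ),
}

#: Driver columns each form requires.
FORM_DRIVERS: Dict[str, tuple] = {
    "flowering": ("dar", "vpd", "ta", "lai"),
    "picking": ("dar", "vpd", "ta", "w"),
    "unsegmented": ("dar", "vpd", "ta", "w", "lai"),
}


# ---------------------------------------------------------------------------
# pointwise evaluation

def _check_positive(name, x):
    if np.any(np.asarray(x) <= 0):
        raise DomainError(f"{name} must be strictly positive for this model form")


def evaluate_flowering(dar, vpd, ta, lai, coefs: Optional[ModelCoefficients] = None):
    """Flowering/fruit-setting form a·DAR^b + c·lnVPD + d·lnTa + e·lnLAI.

    LAI values below ``LAI_FLOOR`` are floored before the log.  Returns the
    raw model value (may be negative); clipping is a reporting decision
    made in :func:`predict_series`.
    """
    coefs = coefs or PUBLISHED["flowering"]
    if coefs.form != "flowering":
        raise ParameterError(f"expected flowering coefficients, got {coefs.form}")
    for name, x in (("dar", dar), ("vpd", vpd), ("ta", ta)):
        _check_positive(name, x)
    dar, vpd, ta = (np.asarray(x, dtype=float) for x in (dar, vpd, ta))
    lai = np.maximum(np.asarray(lai, dtype=float), LAI_FLOOR)
    v = coefs.values
    out = (
        v["a"] * dar ** v["b"]
        + v["c"] * np.log(vpd)
        + v["d"] * np.log(ta)
        + v["e"] * np.log(lai)
    )
    return float(out) if out.ndim == 0 else out


def evaluate_picking(dar, vpd, ta, w, coefs: Optional[ModelCoefficients] = None):
    """Picking-stage form a·DAR^b + c·exp(VPD) + d·lnTa + e·lnW + f.

    Wind speeds below ``W_FLOOR`` are floored before the log.
    """
    coefs = coefs or PUBLISHED["picking"]
    if coefs.form != "picking":
        raise ParameterError(f"expected picking coefficients, got {coefs.form}")
    for name, x in (("dar", dar), ("ta", ta)):
        _check_positive(name, x)
    dar, vpd, ta = (np.asarray(x, dtype=float) for x in (dar, vpd, ta))
    w = np.maximum(np.asarray(w, dtype=float), W_FLOOR)
    v = coefs.values
    out = (
        v["a"] * dar ** v["b"]
        + v["c"] * np.exp(vpd)
        + v["d"] * np.log(ta)
        + v["e"] * np.log(w)
        + v["f"]
    )
    return float(out) if out.ndim == 0 else out


def evaluate_unsegmented(
    dar, vpd, ta, w, lai, coefs: Optional[ModelCoefficients] = None
):
    """Whole-season comparison form, linear in transformed drivers."""
    coefs = coefs or PUBLISHED["unsegmented"]
    if coefs.form != "unsegmented":
        raise ParameterError(f"expected unsegmented coefficients, got {coefs.form}")
    for name, x in (("dar", dar), ("vpd", vpd), ("ta", ta)):
        _check_positive(name, x)
    dar, vpd, ta, lai = (np.asarray(x, dtype=float) for x in (dar, vpd, ta, lai))
    w = np.maximum(np.asarray(w, dtype=float), W_FLOOR)
    v = coefs.values
    out = (
        v["b_dar"] * np.log(dar)
        + v["b_vpd"] * np.log(vpd)
        + v["b_ta"] * np.log(ta)
        + v["b_w"] * np.log(w)
        + v["b_lai"] * np.exp(lai)
        + v["intercept"]
    )
    return float(out) if out.ndim == 0 else out


_EVALUATORS = {
    "flowering": lambda df, c: evaluate_flowering(
        df["dar"], df["vpd"], df["ta"], df["lai"], c
    ),
    "picking": lambda df, c: evaluate_picking(
        df["dar"], df["vpd"], df["ta"], df["w"], c
    ),
    "unsegmented": lambda df, c: evaluate_unsegmented(
        df["dar"], df["vpd"], df["ta"], df["w"], df["lai"], c
    ),
}


def evaluate(form: str, drivers: pd.DataFrame, coefs: ModelCoefficients):
    """Evaluate one model form over a driver table (columns per FORM_DRIVERS)."""
    if form not in _EVALUATORS:
        raise ParameterError(f"unknown model form {form!r}")
    return np.asarray(_EVALUATORS[form](drivers, coefs), dtype=float)


# ---------------------------------------------------------------------------
# stage calendar and segmented prediction

@dataclass(frozen=True)
class StageCalendar:
    """Contiguous stage boundaries on a day axis (ints or timestamps).

    ``flowering_start`` ≤ day < ``picking_start`` is flowering/fruit-setting;
    ``picking_start`` ≤ day ≤ ``end`` is picking (the boundary day belongs
    to picking, a closed-left convention); days before ``flowering_start``
    are seedling.  The LAI-plateau condition that switches the segmented
    model's branches is realised as this calendar: "LAI at its maximum"
    means the canopy has plateaued, i.e. the picking stage has begun.
    """

    flowering_start: object
    picking_start: object
    end: object

    def __post_init__(self):
        if not (self.flowering_start < self.picking_start <= self.end):
            raise ParameterError("calendar intervals must be chronological")

    def stage_of(self, day) -> str:
        if day > self.end:
            raise ParameterError(f"day {day!r} is beyond the calendar end")
        if day >= self.picking_start:
            return "picking"
        if day >= self.flowering_start:
            return "flowering_fruit_setting"
        return "seedling"


def predict_series(
    days: pd.DataFrame,
    calendar: StageCalendar,
    coefs: Optional[Mapping[str, ModelCoefficients]] = None,
    day_col: str = "day",
) -> pd.DataFrame:
    """Segmented prediction over a merged daily driver table.

    Applies the flowering form to flowering/fruit-setting days and the
    picking form to picking days; seedling days are excluded.  Raw
    negative predictions are clipped to 0 and flagged.

    Returns DataFrame with columns ``day, ts, stage, flag``.
    """
    coefs = dict(coefs or {})
    coefs.setdefault("flowering", PUBLISHED["flowering"])
    coefs.setdefault("picking", PUBLISHED["picking"])
    if day_col not in days.columns:
        raise ParameterError(f"driver table has no {day_col!r} column")
    stages = days[day_col].map(calendar.stage_of)
    out_rows = []
    for stage, form in (
        ("flowering_fruit_setting", "flowering"),
        ("picking", "picking"),
    ):
        sub = days.loc[stages == stage]
        if sub.empty:
            continue
        raw = evaluate(form, sub, coefs[form])
        flag = np.where(raw < 0, "negative_clipped", "ok")
        out_rows.append(
            pd.DataFrame(
                {
                    "day": sub[day_col].to_numpy(),
                    "ts": np.where(raw < 0, 0.0, raw),
                    "stage": stage,
                    "flag": flag,
                },
                index=sub.index,
            )
        )
    if not out_rows:
        return pd.DataFrame(columns=["day", "ts", "stage", "flag"])
    return pd.concat(out_rows).sort_index()


# ---------------------------------------------------------------------------
# fitting

def _design_matrix(form: str, drivers: pd.DataFrame, b: float) -> np.ndarray:
    """Design matrix for the conditionally linear coefficients given b."""
    dar = drivers["dar"].to_numpy(dtype=float)
    vpd = drivers["vpd"].to_numpy(dtype=float)
    ta = drivers["ta"].to_numpy(dtype=float)
    if form == "flowering":
        lai = np.maximum(drivers["lai"].to_numpy(dtype=float), LAI_FLOOR)
        return np.column_stack([dar**b, np.log(vpd), np.log(ta), np.log(lai)])
    if form == "picking":
        w = np.maximum(drivers["w"].to_numpy(dtype=float), W_FLOOR)
        return np.column_stack(
            [dar**b, np.exp(vpd), np.log(ta), np.log(w), np.ones_like(dar)]
        )
    raise ParameterError(f"no nonlinear design for form {form!r}")


def _unsegmented_design(drivers: pd.DataFrame) -> np.ndarray:
    dar = drivers["dar"].to_numpy(dtype=float)
    vpd = drivers["vpd"].to_numpy(dtype=float)
    ta = drivers["ta"].to_numpy(dtype=float)
    w = np.maximum(drivers["w"].to_numpy(dtype=float), W_FLOOR)
    lai = drivers["lai"].to_numpy(dtype=float)
    return np.column_stack(
        [np.log(dar), np.log(vpd), np.log(ta), np.log(w), np.exp(lai), np.ones_like(dar)]
    )


class TranspirationModel:
    """One-stage daily-transpiration regression model.

    Parameters
    ----------
    endog
        Observed daily transpiration Tm (mm·d⁻¹), length n.
    exog
        Driver table with the columns the chosen form requires
        (see :data:`FORM_DRIVERS`).
    form
        ``"flowering"``, ``"picking"`` or ``"unsegmented"``.

    Examples
    --------
    >>> model = TranspirationModel.from_dataframe(df, form="flowering")
    >>> res = model.fit()
    >>> res.params["b"]        # doctest: +SKIP
    """

    def __init__(self, endog, exog: pd.DataFrame, form: str):
        if form not in COEF_NAMES:
            raise ParameterError(f"unknown model form {form!r}")
        required = set(FORM_DRIVERS[form])
        missing = required - set(exog.columns)
        if missing:
            raise ParameterError(f"{form} model needs driver columns {sorted(missing)}")
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 1 or len(endog) != len(exog):
            raise ParameterError("endog must be 1-D and aligned with exog")
        n_coef = len(COEF_NAMES[form])
        if len(endog) < 3 * n_coef:
            raise ParameterError(
                f"need at least {3 * n_coef} observations to fit the {form} form"
            )
        self.endog = endog
        self.exog = exog.reset_index(drop=True)
        self.form = form

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, form: str, response: str = "tm"
    ) -> "TranspirationModel":
        if response not in data.columns:
            raise ParameterError(f"data has no response column {response!r}")
        return cls(data[response].to_numpy(dtype=float), data, form)

    def predict(self, params: ModelCoefficients, exog: Optional[pd.DataFrame] = None):
        return evaluate(self.form, self.exog if exog is None else exog, params)

    # -- internals ----------------------------------------------------------

    def _check_rank(self, X: np.ndarray):
        tol = 1e-10 * max(1.0, float(np.abs(X).max()))
        if np.linalg.matrix_rank(X, tol=tol) < X.shape[1]:
            raise MulticollinearityError(
                "design matrix is rank deficient; check for constant or "
                "proportional driver columns"
            )

    def _fit_linear(self) -> "TranspirationResults":
        X = _unsegmented_design(self.exog)
        self._check_rank(X)
        beta, _, _, _ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ beta
        return self._results(beta, resid, jac=X, converged=True, n_iter=1)

    def _fit_nonlinear(
        self, b_starts: Sequence[float], max_nfev: int
    ) -> "TranspirationResults":
        X1 = _design_matrix(self.form, self.exog, 1.0)
        self._check_rank(X1)
        names = COEF_NAMES[self.form]
        b_idx = names.index("b")

        def unpack(theta):
            # theta orders the linear coefficients with b spliced in at b_idx
            return ModelCoefficients.from_array(self.form, theta)

        def residuals(theta):
            return (
                evaluate(self.form, self.exog, unpack(theta)) - self.endog
            )

        best = None
        for b0 in b_starts:
            X = _design_matrix(self.form, self.exog, b0)
            lin, _, _, _ = np.linalg.lstsq(X, self.endog, rcond=None)
            theta0 = np.insert(lin, b_idx, b0)
            try:
                sol = least_squares(
                    residuals,
                    theta0,
                    method="lm",
                    max_nfev=max_nfev,
                    x_scale="jac",
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not sol.success:
                continue
            in_bounds = B_BOUNDS[0] < sol.x[b_idx] < B_BOUNDS[1]
            key = (not in_bounds, sol.cost)  # prefer in-bounds, then lowest cost
            if best is None or key < best[0]:
                best = (key, sol)
        if best is None:
            raise FitError(
                f"{self.form} fit did not converge from any start in {list(b_starts)}"
            )
        (out_of_bounds, _), sol = best
        if out_of_bounds:
            # retry with box constraints on b via trust-region reflective
            lower = np.full(len(names), -np.inf)
            upper = np.full(len(names), np.inf)
            lower[b_idx], upper[b_idx] = B_BOUNDS
            sol = least_squares(
                residuals,
                np.clip(sol.x, lower + 1e-9, upper - 1e-9),
                method="trf",
                bounds=(lower, upper),
                max_nfev=max_nfev,
            )
            if not sol.success:
                raise FitError("bounded refit of the power-law exponent failed")
        resid = sol.fun
        return self._results(
            sol.x, resid, jac=sol.jac, converged=bool(sol.success), n_iter=sol.nfev
        )

    def _results(self, theta, resid, jac, converged, n_iter):
        n, k = len(self.endog), len(theta)
        rss = float(resid @ resid)
        df_resid = n - k
        s2 = rss / df_resid if df_resid > 0 else np.nan
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        names = COEF_NAMES[self.form]
        return TranspirationResults(
            model=self,
            params=pd.Series(theta, index=list(names), name="coef"),
            cov_params=pd.DataFrame(cov, index=list(names), columns=list(names)),
            rss=rss,
            n_obs=n,
            converged=converged,
            n_iter=int(n_iter),
        )

    # -- public fit ---------------------------------------------------------

    def fit(
        self,
        b_starts: Sequence[float] = (0.8, 1.0, 1.3),
        max_nfev: int = 2000,
        method: str = "auto",
    ) -> "TranspirationResults":
        """Estimate coefficients by least squares.

        The unsegmented form is linear after driver transforms and is
        solved in closed form (``method="auto"``); pass ``method="lm"`` to
        force the iterative damped-least-squares path instead (the two
        agree to high precision — a useful cross-check).  Nonlinear forms
        run Levenberg–Marquardt from a small grid of power-law exponents
        ``b_starts`` with conditionally linear coefficients profiled at
        each start; the exponent is constrained to ``B_BOUNDS``.
        """
        if self.form == "unsegmented" and method == "auto":
            return self._fit_linear()
        if self.form == "unsegmented":
            # iterative path for the linear form: single start at the
            # closed-form solution perturbed to exercise the optimizer
            X = _unsegmented_design(self.exog)
            self._check_rank(X)

            def residuals(theta):
                return X @ theta - self.endog

            sol = least_squares(
                residuals, np.zeros(X.shape[1]), method="lm", max_nfev=max_nfev
            )
            if not sol.success:
                raise FitError("unsegmented iterative fit did not converge")
            return self._results(
                sol.x, sol.fun, jac=X, converged=True, n_iter=sol.nfev
            )
        return self._fit_nonlinear(b_starts, max_nfev)


@dataclass
class TranspirationResults:
    """Fit results: named coefficients, covariance, and diagnostics."""

    model: TranspirationModel
    params: pd.Series
    cov_params: pd.DataFrame
    rss: float
    n_obs: int
    converged: bool
    n_iter: int

    @property
    def coefficients(self) -> ModelCoefficients:
        return ModelCoefficients(self.model.form, self.params.to_dict())

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())),
            index=self.params.index,
            name="std err",
        )

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.params)

    @property
    def sigma(self) -> float:
        """Residual standard deviation (mm·d⁻¹)."""
        return float(np.sqrt(self.rss / self.df_resid)) if self.df_resid > 0 else np.nan

    def predict(self, exog: Optional[pd.DataFrame] = None):
        return self.model.predict(self.coefficients, exog)

    def summary(self) -> str:
        lines = [
            f"Daily transpiration model — {self.model.form} form",
            "=" * 52,
            f"n_obs {self.n_obs:>6d}    RSS {self.rss:.6g}    "
            f"sigma {self.sigma:.4g} mm/d",
            f"converged {self.converged}    function evals {self.n_iter}",
            "-" * 52,
            f"{'coef':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<10}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted scatter with the 1:1 line (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fitted = self.predict()
        ax.scatter(self.model.endog, fitted, s=12)
        lim = [0, max(self.model.endog.max(), fitted.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("measured Tm (mm/d)")
        ax.set_ylabel("fitted Ts (mm/d)")
        ax.set_title(f"{self.model.form} model fit")
        return ax


class SegmentedTranspirationModel:
    """Two-stage segmented model over a merged daily table.

    Parameters
    ----------
    data
        Daily table with a ``day`` column, the response column, and all
        driver columns (dar, vpd, ta, w, lai).
    calendar
        :class:`StageCalendar` assigning each day to a stage.
    response
        Name of the observed-transpiration column (default ``"tm"``).
    """

    def __init__(
        self, data: pd.DataFrame, calendar: StageCalendar, response: str = "tm"
    ):
        self.data = data.reset_index(drop=True)
        self.calendar = calendar
        self.response = response
        stages = self.data["day"].map(calendar.stage_of)
        self._flowering = self.data.loc[stages == "flowering_fruit_setting"]
        self._picking = self.data.loc[stages == "picking"]

    def fit(self, **kwargs) -> "SegmentedResults":
        flowering = TranspirationModel.from_dataframe(
            self._flowering, "flowering", self.response
        ).fit(**kwargs)
        picking = TranspirationModel.from_dataframe(
            self._picking, "picking", self.response
        ).fit(**kwargs)
        return SegmentedResults(model=self, flowering=flowering, picking=picking)


@dataclass
class SegmentedResults:
    """Per-stage fit results plus whole-series prediction."""

    model: SegmentedTranspirationModel
    flowering: TranspirationResults
    picking: TranspirationResults

    @property
    def rss(self) -> float:
        return self.flowering.rss + self.picking.rss

    @property
    def n_obs(self) -> int:
        return self.flowering.n_obs + self.picking.n_obs

    def predict(self, data: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        data = self.model.data if data is None else data
        return predict_series(
            data,
            self.model.calendar,
            {
                "flowering": self.flowering.coefficients,
                "picking": self.picking.coefficients,
            },
        )

    def summary(self) -> str:
        return "\n\n".join([self.flowering.summary(), self.picking.summary()])


def fit_stage_model(
    observed, drivers: pd.DataFrame, form: str, **kwargs
) -> TranspirationResults:
    """Functional wrapper: fit one model form to observed daily Tm."""
    return TranspirationModel(observed, drivers, form).fit(**kwargs)
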