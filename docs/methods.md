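# Methods

## Water balance

A weighed substrate unit is treated as closed except for irrigation in,
return flow out, and transpiration: the coir strips are film-wrapped so
substrate-surface evaporation is taken as zero, and plant biomass gain is
neglected at the daily scale.  Daily transpiration per plant unit is then
the morning-to-morning mass balance Td = Wᵢ + Iᵢ − Rᵢ − Wᵢ₊₁ (kg).
Negative balances — condensation or weighing error — are clipped to zero
and flagged `negative_clipped` rather than propagated; nothing downstream
should see a negative water loss.

The depth conversion is the canonical one: Tm (mm·d⁻¹) = Td (kg·plant⁻¹)
× PD (plants·m⁻²), since 1 kg of water over 1 m² is a 1 mm layer.  The
default planting density, 4.76 plants·m⁻², follows from the row geometry
(1.0 m / 0.4 m wide/narrow rows, 0.3 m plant spacing → 1/(0.7 × 0.3) m²
per plant) and is configurable.

The deficit-irrigation rule irrigates when the substrate water store
falls strictly below a fraction of water-holding capacity (0.80 / 0.70 /
0.60 for the three treatments), refilling to capacity.  The boundary case
holds rather than fires; the threshold is a lower *limit*, and the choice
only matters on a set of measure zero.

## Driver variables

VPD is computed per logger reading from the Tetens saturation curve,
e_s = 0.6108·exp(17.27·Ta/(Ta+237.3)) kPa, and *then* averaged to daily
resolution: e_s is convex in Ta, so converting daily-mean Ta/RH instead
would bias the daily VPD low on days with a large temperature range.
Radiation is converted to a water-equivalent depth with a constant latent
heat of 2.45 MJ·kg⁻¹ (the standard agro-meteorological convention; its
temperature dependence is ~1 % over the greenhouse range and not worth a
second parameter).  A day with under 80 % of expected readings is emitted
but flagged `low_coverage`; no gap-filling is attempted.

## Canopy

Single-leaf area is length × maximum width × 0.64, the usual bounding-box
reduction for tomato's compound leaf.  LAI is summed leaf area per plant
(m²) over ground area per plant (default 1/PD = 0.21 m², configurable —
the per-plant ground area is a genuine free choice and any consistent
value cancels out of treatment *comparisons*).  Sparse ~10-day LAI
measurements are interpolated to daily resolution with a shape-preserving
piecewise cubic Hermite interpolant (PCHIP): exact at knots, monotone on
monotone segments, no overshoot — important because the interpolated LAI
feeds a log term.  Extrapolation beyond the measured day range is refused
rather than guessed.

## Segmented transpiration model

Flowering/fruit-setting form: Ts = a·DAR^b + c·ln VPD + d·ln Ta +
e·ln LAI, valid while the canopy expands (LAI from 1 up to its plateau).
Picking form: Ts = a·DAR^b + c·exp(VPD) + d·ln Ta + e·ln W + f, with LAI
dropped (it has plateaued and carries no signal) and wind entering.
Stage switching is by calendar: the "LAI at its maximum" branch condition
is operationalised as "the picking stage has begun", because testing
exact equality of a real-valued LAI is not robust.  The boundary day
belongs to picking (closed-left).

Estimation is damped (Levenberg–Marquardt) least squares.  The model is
conditionally linear given the exponent b, so each start of the small
grid b ∈ {0.8, 1.0, 1.3} profiles the linear coefficients by ordinary
least squares before the joint refinement; Jacobian-based variable
scaling (`x_scale="jac"`) handles the ~10⁵ dynamic range between a and
the other coefficients.  b is constrained to (0.2, 3); if every
unconstrained solution exits that interval the fit is repeated with box
constraints (trust-region reflective).  The best in-bounds solution by
residual sum of squares wins.  Coefficient covariance is s²(JᵀJ)⁻¹ at
the solution.  Negative predictions are clipped to zero *for reporting
only*; the loss sees raw values, since clipping inside the objective
would zero gradients exactly where the fit is worst.

The unsegmented comparison model T′ = β₁ ln DAR + β₂ ln VPD + β₃ ln Ta +
β₄ ln W + β₅ e^LAI + β₆ is linear after transforms and solved in closed
form; the iterative path can be forced (`method="lm"`) and agrees to
better than 10⁻⁶, which the tests use as an oracle equivalence.  Floors
of 0.01 are applied before ln LAI and ln W (greenhouse wind speed sits
near zero and ln 0 is undefined); floored inputs are flagged.

**Plausibility caveat.**  The published picking-stage coefficient set
(a=0.011, b=1.04, c=0.189, d=−0.110, e=5.625, f=−6.01) evaluates to
large negative transpiration at its own stage-mean drivers — the ln W
term and intercept dominate at wind speeds near 0.1 m·s⁻¹ — which points
to a transcription or unit inconsistency in the source constants.  The
functional form is implemented as stated; the constants ship as defaults
with this warning, and every quantitative claim in this package rests on
*refitting* coefficients, never on these values.  A garbled legacy
mass-to-depth expression involving a constant 35.3 was likewise not
reproducible from first principles and is deliberately not implemented;
the canonical PD conversion above replaces it.

### Identifiability of the power-law pair

The prefactor a multiplies DAR^b where observed DAR is O(50–150); a is
therefore the model's value at DAR = 1, about 4.4 ln-units outside the
data, and ln â inherits b̂'s error amplified by the mean ln DAR.  A
Fisher-information (Cramér–Rao) calculation at the default study
conditions — 150 days, 0.05 mm·d⁻¹ noise, radiation CV 0.35 — gives a
lower bound of roughly 60 % relative standard error on a and 0.12 on b,
for *any* estimator, while c, d, e are pinned to 1–3 %.  Tests and the
acceptance report show exactly this pattern: the curvature coefficients
recover within a few percent; a and b carry honest, large uncertainty.
Users needing a stable radiation term should consider the centered
parameterisation a′·(DAR/DAR₀)^b with DAR₀ a typical radiation value —
not done here to keep the published form.

## Predictor screening

Path analysis solves R_xx·P = r_xy for the standardized direct effects P
(equivalently, OLS on z-scored variables — verified against that oracle)
and reports indirect effects r_ij·P_j.  The decomposition identity
r_i = P_i + Σ_{j≠i} r_ij P_j holds to ~10⁻¹⁰ on any full-rank input and
is asserted, which guards both the solver and the standardization
(sample, n−1).  A singular predictor correlation matrix raises an error
naming the most collinear pair.  Driver ranking is by |r| descending,
ties alphabetical and flagged.  Stars: * p<0.05, ** p<0.01.

## Evaluation statistics

MAE, RMSE, MRE = 100·mean(|T−M|/M) %, NSE = 1 − Σ(T−M)²/Σ(M−M̄)², and R²
of the simulated-vs-measured OLS line.  MRE takes absolute errors and
NSE squared sums — the standard definitions; signed or unsquared
variants are dimensionally inconsistent and incompatible with NSE values
inside (0, 1].  MRE is undefined (flagged) when any measured value is
zero; NSE is refused for a constant measured series.  All are verified
to 10⁻¹² against a per-definition loop oracle.

## TOPSIS

Default variant: vector (Euclidean-norm) column normalization, equal
weights, all five indicators (yield per plant, WUE, total soluble
solids, vitamin C, sugar–acid ratio) as benefit criteria; Ci =
D⁻/(D⁺+D⁻), ranked descending, ties sharing the minimum rank with a
flag.  Shannon-entropy weighting is available behind a flag.  The
packaged season tables rank T2 > T3 > T1 in both seasons under the
default variant (2022 Ci ≈ 0.351/0.654/0.629); the *rank order* is the
analysis contract — closeness magnitudes depend on the normalization and
weighting variant chosen, and alternative published distance magnitudes
for these tables are not reproducible from the printed indicators under
any standard variant, so no Ci value is treated as a target.  Yield
enters per plant; using total yield instead leaves the ranks unchanged
for the packaged data.

## Synthetic generator

What it emulates: per-stage climatology (the packaged stage means for
both seasons), day-to-day weather variability and persistence, the
sunny-warm-dry coupling, a logistic canopy trajectory measured on a
10-day schedule with noise, model-driven transpiration with Gaussian
observation error, and gram-resolution weighing records driven by the
deficit trigger rule.

Drivers are lognormal around their stage means: value = mean·exp(s·z −
s²/2) with z a stationary AR(1) anomaly and s = sqrt(ln(1+cv²)), so
values are strictly positive, right-skewed like real daily radiation,
and the configured arithmetic mean and CV are exact.  Defaults: cv =
0.35 (overcast days commonly halve daily radiation), lag-1
autocorrelation 0.5 (synoptic persistence of a few days), DAR→VPD/Ta
anomaly coupling 0.6.  Temperature uses 0.3× and wind 0.8× the
configured cv — a glasshouse buffers daily-mean temperature far more
than radiation.  These variability settings are plausible-realistic
choices, not measured values; only the stage means are data.

LAI truth is logistic (lai_max 2.64, midpoint day 46, rate 0.115 d⁻¹,
matching the mid irrigation treatment's measured trajectory); the
growth data show sigmoid rise to a plateau but fix no functional form,
so logistic is a generator choice.  The slight late-season LAI decline
visible in measurements is not emulated.

Weighing records quantise all masses and the encoded transpiration to a
2⁻¹⁰ kg grid (≈1 g, the scale's resolution).  Because these dyadic
values are exactly representable and their sums stay far below 2⁵³,
every mass-balance identity is *exact* in double precision and the
water-balance extraction recovers the encoded series bit for bit — the
round-trip test runs at zero tolerance, deliberately.

What it does not emulate: sub-daily dynamics, radiative/energy-balance
greenhouse physics, seasonal trends within a stage (drivers are
stationary around the stage mean), stomatal responses to water stress,
or measurement drift.  Passing tests therefore demonstrate the
*pipeline's* correctness and the estimator's behaviour under the stated
noise model — not the transferability of any coefficient set to a real
greenhouse.

## Problem sizes

Defaults used by tests and the acceptance script: 150 days per recovery
replicate (5 replicates), 1000 days for moment-emulation checks, 100
random vectors for metric oracles, 200 days for the weighing
round-trip.  These sizes give sampling error comfortably below the
asserted tolerances while the whole suite runs in seconds.

## Known limitations

* The power-law prefactor is weakly identified at realistic radiation
  ranges (see above); treat fitted (a, b) jointly, e.g. via their
  covariance, never marginally.
* The published picking-stage and unsegmented coefficient sets are
  retained verbatim for reference but fail a basic plausibility check at
  stage-mean drivers; refit before use.
* Treatment-level tables carry three replicates' means only; the package
  does not attempt significance testing of treatment differences.
* MRE is undefined on days with zero measured transpiration, which do
  occur in clipped weighing data; the flag must be checked.
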