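# Methods

## The accounting model

All estimators share one bookkeeping identity over the 240-s supramaximal
time trial, discretised at 1 Hz:

```
MR_an,t = MR_req,t − MR_ae,t          [W·kg⁻¹ system mass]
E_an    = Σ_t MR_an,t · 1 s           (rectangle rule)
ΣO2 deficit = E_an × 0.047801 mL·J⁻¹
```

The accumulated demand therefore always equals accumulated aerobic energy
plus E_an, exactly — there is no quadrature choice beyond the 1-Hz
rectangle rule, which matches the per-second resolution of the input
series. Device data logged at other rates (e.g. 2.46 Hz) are linearly
interpolated onto integer seconds first. Negative per-second and total
deficits are legitimate outputs and are never clipped.

The aerobic side `MR_ae,t` is the Weir conversion of measured VO₂,
`MR = 4184·V̇O₂·(1.1·RER + 3.9)/60`, with RER clamped at 1.00 by default:
above the second ventilatory threshold, bicarbonate buffering of lactic
acid adds non-metabolic CO₂, so a measured RER of 1.10–1.15 no longer
reflects substrate mix. The clamp is a flag (`clamp_rer`) because the
choice is a convention, not a measurement; clamping can only lower MR_ae
and hence can only raise the deficit. The same RER = 1.00 convention
defines the peak aerobic metabolic rate (from VO₂peak, the highest 30-s
moving average of the trial) and the 0.047801 mL·J⁻¹ O₂ equivalence, which
is held in the code as the exact expression 1000/(4184·(1.1 + 3.9)) rather
than the rounded literal.

## The demand side: six estimators plus one

The four MAOD variants regress stage metabolic rate (W·kg⁻¹ system mass)
on stage speed (km·h⁻¹) — linear or second-degree polynomial, with or
without the standing-baseline rate — and evaluate the fit at each second's
time-trial speed. Two modelling conventions deserve note:

- **Baseline inclusion is an appended data point, not a forced intercept.**
  The "+Y" variants add (0 km·h⁻¹, MR_baseline) to the regression data and
  estimate the intercept freely. The alternative reading (pinning the
  intercept at the measured baseline) is inconsistent with the linear and
  polynomial "+Y" variants having different fitted intercepts, which is
  what per-athlete fits produce in practice.
- **Goodness of fit.** SEE uses residual degrees of freedom n − p (n − 2
  linear, n − 3 quadratic); r² is the ordinary coefficient of
  determination. Regressions can equivalently be parameterised against
  power output — power is proportional to speed on a fixed incline, so the
  two differ only by a scale on the slope; the speed basis matches how
  coefficients are conventionally reported.

The fixed-GE variants divide the instantaneous mechanical power per kg by
a constant gross efficiency: the unweighted mean of the eight stage GEs
(GE_AVG; stage durations are nearly equal and no weighting is standard) or
the last stage's GE (GE_LAST). The regression-implied efficiency GE_REG =
power/(predicted rate) links the two families: for a linear demand model,
GE_REG is speed-independent exactly when the intercept is zero, increasing
in speed for a positive intercept and decreasing for a negative one. That
geometry explains both the systematic MAOD-vs-GE differences (a positive
intercept lowers the extrapolated demand relative to a fixed-GE demand,
and conversely) and why the intercept across athletes linearly predicts
the per-athlete (MAOD − GE_AVG) deficit difference with a negative slope —
a relation the test suite verifies at r² > 0.7 on simulated cohorts.

The lactate-based alternative, (Δlactate × 3 mL·kg⁻¹ per mmol·L⁻¹) ÷ 0.67,
is included as a clearly-labelled seventh estimator. It is defined per kg
*body* mass; when results are reported on the system-mass basis (the
default, since the treadmill power model acts on athlete plus equipment)
it is rescaled accordingly. A `basis` option switches all per-kg outputs
to body mass.

## Synthetic cohorts and what they do (and do not) show

Raw gas-exchange data for this protocol are not publicly deposited, so
estimator validation is by parameter recovery on synthetic athletes:

- **True demand curve** per athlete: linear for diagonal-stride-like
  scenarios (speed-independent GE), convex quadratic for double-poling-like
  scenarios (speed-dependent GE). Scenario means are the curves implied by
  published group-mean stage energy costs (DS ≈ −0.24 + 1.88v; DP ≈ 9.06 −
  0.37v + 0.0343v² W·kg⁻¹ with v in km·h⁻¹); between-athlete spreads mirror
  reported coefficient SDs.
- **Stages**: steady-state rate = demand × (1 + ε), ε ~ N(0, σ) with σ =
  0.02 by default (comparable to the ~1–2% residual scatter of
  near-perfect published stage fits); VO₂ is back-solved through the Weir
  equation under a monotone RER schedule 0.89 → 0.95, so the analysis
  conversion is exact by construction.
- **Time trial**: the aerobic rate relaxes mono-exponentially (τ = 25 ± 4 s,
  a conventional onset time constant) toward the demand capped at the
  VO₂peak ceiling; VO₂peak is drawn per kg body mass (66/69 ± 4 mL·kg⁻¹·
  min⁻¹ for DP/DS) so the ceiling co-scales with mass like the demand. A
  slow-component amplitude parameter exists but defaults to zero. The
  constant trial speed is solved (Brent) so the accounting deficit equals
  the athlete's anaerobic budget (0.85 ± 0.25 / 1.17 ± 0.18 kJ·kg⁻¹ for
  DP/DS); the recorded truth is the exact 1-Hz accounting sum. Recorded TT
  RER is 1.10–1.15, deliberately above 1.00 so the clamping path is always
  exercised, while recorded VO₂ inverts the RER-1.00 conversion so a
  clamped analysis recovers the simulated aerobic rate exactly.
- **Lactates**: post = pre + (true deficit, body-mass basis) × 0.67/3,
  i.e. the exact inverse of the lactate estimator.
- Cohorts default to n = 16; every draw is from a seeded generator and
  rare infeasible parameter combinations (submaximal demand at or above
  the ceiling) are redrawn deterministically.

What passing recovery tests shows: the estimators implement their
definitions correctly, and the *structural* disagreements between methods
(chord-vs-parabola extrapolation on convex demand; intercept-driven
MAOD-vs-GE bias) are real consequences of the definitions, not bugs. What
they do not show: behaviour under breath-by-breath measurement noise,
VO₂ drift/slow components, day-to-day biological variation, or pacing
dynamics — the generator's trials are constant-speed and its noise model
is a single multiplicative stage term.

## Agreement statistics

Differences are a − b with sample SD (n − 1 divisor) throughout. Limits of
agreement are mean ± 1.96·SD(d); the mean difference is tested with a
two-sided one-sample t-test against zero; typical error is SD(d)/√2;
Hedges' g_av standardises mean(d) by √((SD(a)² + SD(b)²)/2) with the
small-sample correction 1 − 3/(4(n−1) − 1); RMSE of regression-implied vs
measured GE is computed per athlete over the eight stages in percentage
points; the within-athlete CV is 100·SD/mean of the eight stage GEs.
Cohort-level repeated-measures ANOVA machinery is deliberately out of
scope — the deliverable is the per-pair comparison grid.

## Numerical and degenerate-input choices

- OLS via `numpy.linalg.lstsq` on an explicit Vandermonde design; rank
  deficiency (duplicate speeds) and insufficient points (< 3 linear, < 4
  quadratic, counting stages only) raise errors. Tiny negative r² from
  round-off on perfect fits is clipped to [0, 1].
- Delta efficiency is the reciprocal slope of the rate-on-power line; a
  slope within 1e−12 (relative to the data scale) of zero is an error.
- Extrapolation beyond the fitted speed range is the MAOD method itself
  and is permitted, but flagged via `DemandModel.is_extrapolating`.
- Zero-length or misaligned series, non-monotone timestamps, RER outside
  [0.6, 1.3], non-positive GE and rate ≤ baseline in net efficiency all
  raise `ValueError` rather than propagating NaN.
- Analysis problem sizes: simulated cohorts of 16 athletes × 240-s trials;
  the full simulate→fit→estimate→compare pipeline and the test suite run
  in seconds.

## Known limitations

- The per-kg basis of published capacity tables is not always explicit;
  this package defaults to system mass (consistent with rates "relative to
  system mass") and exposes `basis="body"`.
- The τ→0 and closed-form kinetics checks tolerate the ~2% gap between the
  1-Hz rectangle sum and the continuous-time integral; the accounting
  identity itself is exact at 1 Hz.
- The lactate estimator inherits the 3 mL·kg⁻¹ per mmol·L⁻¹ and 67%
  constants as fixed conventions; both are exposed as arguments.
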