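# Methods

## The measures

For a nonnegative duration `T` with survivor function `S(t) = Pr{T > t}`,
the package computes

- **CRE** `= -∫ S(t) log S(t) dt`, the cumulative residual entropy: a
  differential entropy on the survivor function. It is nonnegative,
  vanishes exactly for a point mass, is invariant to location shifts
  (`CRE(T + c) = CRE(T)`), scales linearly (`CRE(aT) = a·CRE(T)`), and —
  unlike the density-based `-∫ f log f` — its plug-in estimate on the
  empirical survivor converges to the population value. Units:
  time × information (ms × nats by default). For an exponential of rate
  λ, `CRE = 1/λ` in nats: the total entropy equals the mean.
- **CRE density** `ε′(t) = -S(t) log S(t)`: the integrand above, a
  probability-weighted momentary entropy with global maximum `1/e` nats
  at `S = 1/e`.
- **iCRE(t)** `= -log S(t)`: the unweighted information gained from the
  stimulus by time `t`. It is 0 while `S = 1`, grows without bound as
  `S → 0`, and is numerically identical to the integrated hazard
  `H(t) = ∫₀ᵗ f/S`; the package computes both through the same `-log S`
  identity, so the equality is exact on shared grids.
- **Information-gain rate**: the OLS slope of `iCRE(t)` against `t`
  (statsmodels OLS; slope, intercept, standard error and residual sum of
  squares are reported). For an exponential the curve is exactly linear
  with slope λ; for the ex-Gaussian the curve is asymptotically linear
  with slope `1/τ`.

Information units are configurable: bits (log₂), nats (ln), bans
(log₁₀); `convert_units` rescales exactly (1 ban = log₂10 ≈ 3.322 bits).
All shipped study defaults use the natural logarithm, under which the
exponential CRE equals the mean and the ex-Gaussian rate equals `1/τ`;
results in bans are these values divided by ln 10.

## Parametric models

`ExGaussian(mu, sigma, tau)` (ms): evaluation delegates to
`scipy.stats.exponnorm`, the numerically stable exp-log form of the
Gaussian-CDF closed form; the test suite cross-checks it against a
brute-force numeric convolution of the Gaussian and exponential
densities. `Exponential(lam)` wraps `scipy.stats.expon`. Parameter
validation is strict (`sigma, tau, lam > 0`); degenerate limits are
rejected rather than approximated.

Sampling is seeded and reproducible (`numpy.random.default_rng`); a seed
is mandatory. The ex-Gaussian sampler redraws the rare draws ≤ 0
(conditioning on positivity, since durations are positive by
definition); at the study's parameter sets this affects under 1e-4 of
the probability mass.

## Empirical estimation

The empirical survivor is the ECDF complement `#(T > t)/n`:
right-continuous, `S = 1` before the first observation, `S = 0` at and
after the largest, ties collapsed into single steps. (With no censoring
this coincides with the Kaplan–Meier estimate, which the tests use as an
independent cross-check.)

Plug-in CRE:

- `step` (default): the exact piecewise-constant sum
  `Σ (-S_k log S_k)(t_{k+1} - t_k)`, anchored at `(0, 1)`. Preferred —
  no interpolation error.
- `linear` / `natural_spline`: the survivor is interpolated through the
  post-drop corner points and integrated by trapezoidal quadrature on a
  uniform grid (10,000 intervals by default). A natural cubic spline can
  overshoot and wiggle, so its values are clipped to [0, 1] and projected
  onto the nonincreasing cone by decreasing isotonic regression (pool
  adjacent violators). A running-minimum repair was rejected: it lets a
  single between-knot dip clamp the entire tail and loses several percent
  of the integral at n = 10⁴, whereas PAVA pools violations locally; the
  measured spline-vs-linear CRE difference is ~2% at n = 10⁴ (asserted
  at 3% in the tests).

The empirical survivor is exactly 0 beyond the largest observation, so
the plug-in integral is insensitive to any upper limit past it; this
right-truncation makes the plug-in CRE slightly biased relative to the
population value at finite n (≈1–2% at n = 10⁴ for the study's
conditions), vanishing as n grows — the study report tabulates exact and
plug-in values side by side so the bias is visible.

## The slope fit window

The empirical iCRE is evaluated at the sorted observations (the largest,
where `S = 0` and iCRE diverges, is excluded and counted). The
information-gain rate is fitted by unweighted OLS over the **last 10% of
curve points** (`fit_lower_quantile = 0.9`). Rationale: the rate of a
right-skewed duration model is a tail property — the iCRE only becomes
linear once the Gaussian onset has passed — and a full-window fit mixes
in the curved onset and biases the rate downward severely (for an
ex-Gaussian with σ = 100, τ = 60 the full-window slope is ≈0.008 nats/ms
against a true tail rate of 0.0167). The upper decile sits safely inside
the linear regime at n = 10⁴ while keeping ~10³ points in the fit. Both
`fit_lower_quantile` and `trim_upper_quantile` (default 0; drops the
noisy extreme tail, where few observations survive and the curve becomes
jerky) are exposed for sensitivity analysis. For exactly linear curves
the window choice is irrelevant and the fit recovers λ to machine
precision.

## Numerical conventions

- Quadrature: trapezoidal rule on the tabulated grid. Default grids:
  [0, 2500] ms at 1 ms steps for ex-Gaussian curves (the survivor at
  2500 ms is below e⁻³⁰ for all study conditions, so the truncation
  error is negligible); [0, 30] at 0.01 steps for the exponential
  scenarios.
- The integrand `-S log S` is defined as exactly 0 at `S ∈ {0, 1}` (its
  analytic limit), so no NaNs propagate from the flat head or the tail.
- Points with `S < 1e-12` are excluded from `-log S` and hazard
  computations and counted in the result metadata (`excluded_tail`).
- Curve containers validate their invariants on construction (grids
  strictly increasing; survivor/CDF in [0, 1] and monotone; `F + S = 1`
  exact by construction).

## The simulation study

Six registered conditions: ex-Gaussian baseline (μ=400, σ=30, τ=60 ms)
and one single-parameter manipulation each (μ=800, σ=100, τ=120), plus
exponentials with rates 0.5 and 0.9. Defaults: n = 10,000 per condition
— large enough that plug-in bias and slope noise sit in the low percent
range while the full study runs in seconds — with per-condition seeds
spawned deterministically from a fixed base seed (1234), so the shipped
report is bit-for-bit reproducible. `run_study` reports exact
(quadrature) and empirical CRE and slope per condition plus ratios
against the baseline. Expected qualitative pattern, stable across seeds:
the μ shift changes neither CRE nor slope; raising σ raises CRE
(66.3 → 108.3 nats·ms exactly) but barely moves the rate; doubling τ
raises CRE (66.3 → 123.4) and halves the rate (0.0167 → 0.0083
nats/ms). Condition comparison is by difference and ratio; no
inferential test is implemented.

What the generator emulates: clean, uncensored, stationary samples from
the stated parametric families. What it does not: contaminant fast
guesses or lapses, censoring/timeouts, sequential dependence, and
parameter heterogeneity across trials — so passing tests demonstrate
estimator correctness under the model, not robustness of conclusions on
messy experimental data.

## Limitations

- No parameter fitting: the package simulates from given parameters and
  estimates entropy functionals nonparametrically; it does not fit
  ex-Gaussian parameters to data.
- No censoring support: the empirical survivor assumes every trial
  terminated.
- The iCRE tail is noisy (few surviving observations), which inflates
  slope variance when `trim_upper_quantile = 0`; the default upper-decile
  window at n = 10⁴ keeps the per-seed slope SD near 5%.
- CRE carries the time unit of the input (ms throughout); no implicit
  unit conversion is performed, including for hazard-in-bits rescaling
  (`h/ln 2`, per configured time unit).
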