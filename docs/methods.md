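# Methods

## Model and assumptions

The package assumes short-time Malthusian growth: over a 0–72 h window a
cell population under fixed conditions (including a fixed drug dose) changes
as `N(t) = N0·e^{r·t}`, with the *effective growth rate* `r` absorbing both
division and death. MTT absorbance is taken as proportional to viable
population, so log absorbance normalized to the seeding-time reading is
linear in time with slope `r`. The assumption is checked, not presumed: each
series must pass an exponentiality screen before indices are computed.

Dose dependence of the rate is modeled as a shifted exponential,

    r(C) + r_inf = A · e^(−α·C),

with `A > 0` (days⁻¹), `α > 0` (per concentration unit) and `r_inf > 0` the
magnitude of the negative plateau that the rate approaches at high dose
(cells dying at a dose-independent maximal rate). The model is monotone
decreasing, has control rate `r0 = A − r_inf`, and inverts in closed form,

    C(r) = −(1/α) · ln((r + r_inf) / A),   defined for −r_inf < r ≤ r0.

Note the inversion uses `r + r_inf`: with `r_inf` stored as the positive
plateau magnitude this is the algebraic inverse of the model above, and it
is the form under which the worked example reproduces.

Indices: `ICr0 = C(0)`, `ICrmed = C(r0/2)`, and a growth-rate-derived
`IC50 = C(r0 + ln(V)/t)` with `V = 0.5`, `t = 3` days by default (the
−0.2310 days⁻¹ offset); `V`, `t` and the initial-population ratio are
configurable. `IC50` retains a nominal endpoint by definition; `ICr0` and
`ICrmed` do not.

## Growth-rate stage

* **Normalization** is per independent experiment: every absorbance is
  divided by the *geometric* mean of that experiment's t0 readings, then
  log-transformed. The geometric mean (arithmetic mean in log space) makes
  the t0 log-values average exactly to zero and renders the normalization
  exactly invariant to an experiment-wide rescaling of absorbance units;
  with an arithmetic mean both hold only approximately.
* **Fitting** pools all normalized replicates of all experiments into one
  unweighted OLS fit of log value vs. time (a per-experiment mode is
  available). The t0 points are included with a free intercept; a
  `--exclude-t0` flag drops them from the fit (they still define the
  normalization). Including t0 uses all information and is the default.
* **Bootstrap**: paired (empirical) resampling of (time, log-value) pairs by
  default, or residual resampling with the design held fixed; 1000
  resamples. The rate estimate is the mean bootstrap slope, its SE the
  bootstrap SD, and the default CI the normal approximation
  `r̄ ± z_{α/2}·SE` at 90 % (z = 1.6449); percentile CIs are available.
  Paired resamples that collapse onto a single time point are redrawn
  (capped at 10× the number of resamples). All resampling is vectorized and
  driven by explicit seeds; the pipeline spawns per-concentration sub-seeds
  deterministically from one master seed.
* **Exponentiality check**: when the fitted log-change over the window is
  appreciable (|slope|·Δt > 0.1), the series passes iff the log-linear R² ≥
  0.90 (threshold configurable). Near zero growth R² is uninformative — a
  flat noisy series has R² ≈ 0 yet is perfectly consistent with r ≈ 0 — so
  flat series are rejected only if a quadratic time term absorbs more than
  half the linear fit's residual variance (systematic curvature). The CLI
  escalates failed checks to a non-zero exit unless `--force`.
* **Normality screen** of the bootstrap slope distribution uses moment
  thresholds (|skewness| < 0.5, |excess kurtosis| < 1) rather than a formal
  test: at 1000 resamples formal tests reject for trivially small
  departures.

## Dose–response stage

* The shifted exponential is fitted by unweighted nonlinear least squares.
  Starting values come from the semilog linearization: shift rates by a
  provisional floor `max(−min r, 10⁻³) + 0.1·spread`, then regress
  `ln(r + floor)` on `C` for the decay. Bounds keep `A, α > 0` and the floor
  above `−min(r) + 10⁻⁶` so the inversion's logarithm stays defined at the
  observed minimum rate. Degenerate inputs (all rates equal), optimizer
  failure, or a fit no better than the flat model yield `converged = False`
  rather than an exception.
* **Uncertainty propagation** is the mixed bootstrap/Monte-Carlo scheme:
  concentrations fixed, one rate per concentration drawn from
  `Normal(r̄, SE)`, refit, invert; 1000 draws by default (1000–5000 is
  sensible). The per-draw fit is unweighted — uncertainty enters only
  through the sampling of rates; weighting the fit by SE as well would
  double-count it. Target rates are resolved per draw from the *sampled*
  control rate (`ICrmed` target is half the sampled `r0`, not half the point
  estimate), so control uncertainty propagates into every index. Draws whose
  fit fails or whose target falls outside the attainable range are dropped
  and counted, never redrawn (redrawing would bias toward easy fits); an
  index with ≥ 20 % failed draws is flagged invalid. Reported CIs are 90 %
  percentile intervals of the draw distribution (normal-approximation
  intervals available). The Monte-Carlo index distributions are mildly
  right-skewed, so the reported mean sits slightly above the point-fit
  inversion; this is a property of the procedure, not a bias introduced
  here.
* **Reduced endpoints**: the same pipeline can be restricted to a subset of
  observation times containing t0 (e.g. {0, 72 h}), where the growth rate
  comes from a two-point-per-replicate fit. On exponential data this changes
  the indices only through precision, not location.

## Viability baseline

Endpoint viability is mean treated absorbance over mean same-time control
absorbance × 100. The 4PL sigmoid is fitted in linear concentration space
with the C = 0 control mapped to (smallest positive dose)/100 — the control
anchors the top plateau but has no position on a log-dose axis. For
decreasing-viability data a fitted Hill slope ≤ 0 marks the fit
non-converged; a flag records whether the fitted IC50 lies inside the tested
dose range. No attempt is made to replicate any specific commercial tool's
CI machinery.

## Synthetic data generator

`SyntheticSpec` emulates the standard design the package targets: readings
at 0/24/48/72 h, 3 technical replicates × 3 independent experiments, 11
concentrations (control plus ten two-fold dilutions from 50), ground-truth
dose-response `(A, α, r_inf) = (0.85, 0.06, 0.55)` — control rate
0.30 days⁻¹ — and multiplicative log-normal noise on absorbance with
σ = 0.08. Log-normal noise keeps absorbance positive and makes log-space
residuals homoscedastic, matching the fitting model; an additive-noise
option exists to stress-test robustness. Closed-form index values from the
generating parameters serve as the oracle for end-to-end tests.

What the generator does *not* emulate: plate-position (edge) effects,
density-dependent growth saturation, heteroscedastic reader noise at low
OD, pipetting error correlated within dilution series, and blank-correction
error. Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to every
real-plate artifact; the exponentiality check is the runtime guard against
the most consequential violation (non-exponential growth).

## Numerical choices and problem sizes

Defaults: 1000 bootstrap resamples, 1000 Monte-Carlo draws, 90 % confidence.
The test suite exercises the pipeline at these or smaller sizes (bootstrap
200–1000, Monte-Carlo 200–1000, 20-seed end-to-end recovery at σ = 0.05,
200-repeat CI-coverage simulation), chosen as the smallest sizes at which
the checked properties are stable. OLS slopes are computed from centered
sums; a constant series has slope 0 and R² defined as 1 (the fit is exact).
Equality at the inversion's upper boundary (target rate = control rate)
returns C = 0; rates at or below the floor raise.

## Known limitations

* The shifted exponential is the only dose–response form; log-logistic or
  Weibull alternatives are out of scope.
* Gaussian sampling of rates in the Monte-Carlo stage relies on the
  normality screen of the bootstrap distribution; heavy-tailed rate
  estimates would propagate poorly.
* Pooling experiments assumes a shared true rate per concentration;
  between-experiment rate heterogeneity inflates the bootstrap SE rather
  than being modeled hierarchically.
* Wide-dialect input supports one 96-well plate per time point with an
  explicit layout file; vendor binary exports and well-inference heuristics
  are out of scope, as are blank and edge-effect corrections.
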