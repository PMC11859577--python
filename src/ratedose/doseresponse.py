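"""Shifted-exponential dose-response model and time-independent potency indices.

The effective growth rate declines with drug concentration as

    r(C) = A·e^{-alpha·C} - r_inf

with amplitude A > 0 (days^-1), decay alpha > 0 (per concentration unit) and
r_inf > 0 the magnitude of the negative high-dose plateau. Inverting the model
gives the concentration producing any attainable growth rate,

    C(r) = -(1/alpha) · ln((r + r_inf) / A),

which defines three potency indices:

* **IC50** — concentration at the rate corresponding to 50 % viability at a
  chosen endpoint, r_IC50 = r0 + ln(0.5)/t (−0.2310 days^-1 offset for t = 3);
* **ICr0** — concentration where the growth rate is zero (cytostasis);
* **ICrmed** — concentration where the rate is half the control's.

Index uncertainty is propagated by a mixed bootstrap / Monte-Carlo scheme:
concentrations are held fixed, one rate per concentration is drawn from the
Gaussian summary of its bootstrap slope distribution, the model is refitted
and inverted, and the index distribution over draws is summarized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .assay_io import AssayTable
from .growth import GrowthRateEstimate, estimate_growth_rates

__all__ = [
    "DoseResponseFit",
    "IndexEstimate",
    "ShiftedExponentialDoseResponse",
    "MonteCarloIndexEstimator",
    "fit_shifted_exponential",
    "invert_concentration",
    "rate_for_viability",
    "monte_carlo_indices",
    "reduced_endpoint_indices",
    "analyze_assay",
]

#: ln(0.5)/3 — the rate offset for 50 % viability at the canonical 3-day endpoint
HALF_VIABILITY_OFFSET_3D = math.log(0.5) / 3.0


@dataclass
class DoseResponseFit:
    """Fitted parameters of r(C) = amplitude·e^{-decay·C} - floor."""

    amplitude: float   # A, days^-1
    decay: float       # alpha, per concentration unit
    floor: float       # r_inf, magnitude of the negative plateau, days^-1
    rss: float
    converged: bool

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.amplitude * np.exp(-self.decay * c) - self.floor

    @property
    def rate_at_zero(self) -> float:
        return self.amplitude - self.floor


def _model(c, amplitude, decay, floor):
    return amplitude * np.exp(-decay * c) - floor


def fit_shifted_exponential(concentrations, rates, maxfev: int = 10000) -> DoseResponseFit:
    """Unweighted nonlinear least squares of rates on the shifted exponential.

    Initial guesses follow the semilog linearization: after shifting rates by
    a provisional floor so all are positive, ln(rate + floor) is linear in C
    with slope -decay. Bounds keep A and alpha positive and keep the floor
    above -min(rates) so the inversion's logarithm stays defined at the
    data's minimum rate.

    A fit that is degenerate (all rates equal), that fails to converge, or
    that does not beat the flat (constant-rate) model is returned with
    ``converged=False`` rather than raising.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and rates must have equal length")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit the model")
    if not np.any(np.isclose(c, 0.0)):
        raise ValueError("a zero-concentration (control) rate is required")

    spread = float(r.max() - r.min())
    if spread == 0.0 or np.allclose(r, r[0]):
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan, False)

    floor0 = max(-float(r.min()), 1e-3) + 0.1 * spread
    r0_obs = float(r[np.argmin(c)])
    amplitude0 = r0_obs + floor0
    shifted = r + floor0
    ok = shifted > 0
    if ok.sum() >= 2 and len(np.unique(c[ok])) >= 2:
        slope = np.polyfit(c[ok], np.log(shifted[ok]), 1)[0]
        decay0 = max(-float(slope), 1e-4)
    else:
        decay0 = 1.0 / max(float(c.max()), 1.0)

    floor_lb = -float(r.min()) + 1e-6
    lower = [1e-12, 1e-12, floor_lb]
    upper = [np.inf, np.inf, np.inf]
    p0 = [max(amplitude0, 1e-6), decay0, max(floor0, floor_lb + 1e-6)]
    p0 = [min(max(p, lo + 1e-12), 1e6) for p, lo in zip(p0, lower)]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_model, c, r, p0=p0,
                                         bounds=(lower, upper), maxfev=maxfev)
    except (RuntimeError, ValueError):
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan, False)

    amplitude, decay, floor = (float(v) for v in popt)
    resid = r - _model(c, amplitude, decay, floor)
    rss = float(np.dot(resid, resid))
    flat_resid = r - r.mean()
    rss_flat = float(np.dot(flat_resid, flat_resid))
    converged = (np.isfinite(popt).all() and amplitude > 0 and decay > 0
                 and rss < rss_flat)
    return DoseResponseFit(amplitude, decay, floor, rss, bool(converged))


def invert_concentration(fit: DoseResponseFit, target_rate: float) -> float:
    """Concentration at which the fitted model predicts ``target_rate``.

    Defined for -floor < target_rate <= rate at C=0 (the model's attainable
    range on C >= 0); the upper boundary returns exactly 0.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged dose-response fit")
    if target_rate <= -fit.floor:
        raise ValueError(
            f"target rate {target_rate:g} is at or below the asymptotic floor "
            f"{-fit.floor:g}: concentration undefined")
    r_at_zero = fit.rate_at_zero
    if target_rate > r_at_zero:
        raise ValueError(
            f"target rate {target_rate:g} exceeds the zero-dose rate "
            f"{r_at_zero:g}: not reached by any positive dose")
    if target_rate == r_at_zero:
        return 0.0
    return float(-math.log((target_rate + fit.floor) / fit.amplitude) / fit.decay)


def rate_for_viability(r0: float, viability: float, t: float,
                       n0_ratio: float = 1.0) -> float:
    """Growth rate of a treated population showing ``viability`` at time ``t``.

    From V(t) = (N0C/N0*)·e^{(rC - r0)·t}: rC = r0 + ln(V·N0C/N0*)/t.
    With V = 0.5, t = 3 days and equal initial populations this is
    r0 + ln(0.5)/3 = r0 - 0.2310.
    """
    if viability <= 0:
        raise ValueError("viability must be positive")
    if t <= 0:
        raise ValueError("time must be positive")
    if n0_ratio <= 0:
        raise ValueError("initial-population ratio must be positive")
    return r0 + math.log(viability * n0_ratio) / t


@dataclass
class IndexEstimate:
    """Monte-Carlo summary of one potency index."""

    index_name: str
    target_rate: float          # target at the point-estimate rates
    mean: float                 # mean of the MC concentration distribution
    ci_low: float
    ci_high: float
    mc_values: np.ndarray       # successful draws only
    n_sims: int
    n_failed: int
    valid: bool = True
    message: str = ""


_TargetRule = Callable[[float], float]  # sampled r0 -> target rate


def _index_rules(index_specs, viability: float, t: float,
                 n0_ratio: float) -> list[tuple[str, _TargetRule]]:
    rules: list[tuple[str, _TargetRule]] = []
    for spec in index_specs:
        if isinstance(spec, tuple):
            rules.append(spec)
            continue
        name = str(spec)
        if name.upper() == "IC50":
            offset = math.log(viability * n0_ratio) / t
            rules.append((name, lambda r0, off=offset: r0 + off))
        elif name.upper() == "ICR0":
            rules.append((name, lambda r0: 0.0))
        elif name.upper() == "ICRMED":
            rules.append((name, lambda r0: r0 / 2.0))
        else:
            raise ValueError(f"unknown index {name!r}; pass (name, rule) for custom indices")
    return rules


def _coerce_rate_table(rate_estimates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(rate_estimates, pd.DataFrame):
        df = rate_estimates
        conc = df["concentration"].to_numpy(dtype=float)
        means = df["rate_mean"].to_numpy(dtype=float)
        ses = df["rate_se"].to_numpy(dtype=float)
    else:
        conc = np.array([e.concentration for e in rate_estimates], dtype=float)
        means = np.array([e.rate_mean for e in rate_estimates], dtype=float)
        ses = np.array([e.rate_se for e in rate_estimates], dtype=float)
    order = np.argsort(conc)
    return conc[order], means[order], ses[order]


def monte_carlo_indices(rate_estimates, index_specs=("IC50", "ICr0", "ICrmed"),
                        n_sims: int = 1000, seed: int | None = None,
                        conf_level: float = 0.90, viability: float = 0.5,
                        t: float = 3.0, n0_ratio: float = 1.0,
                        ci_method: str = "percentile",
                        max_failed_fraction: float = 0.2,
                        return_draws: bool = False):
    """Mixed bootstrap / Monte-Carlo estimation of the potency indices.

    For each of ``n_sims`` draws, one rate per concentration is sampled from
    Normal(rate_mean, rate_se) with concentrations held fixed, the shifted
    exponential is refitted, and each requested index is obtained by
    inversion; target rates are resolved per draw from the *sampled* control
    rate, so control uncertainty propagates into every index. Draws whose
    fit fails or whose inversion is undefined are dropped and counted; an
    index with more than ``max_failed_fraction`` failures is flagged invalid.

    ``rate_estimates`` may be a list of :class:`GrowthRateEstimate` or a
    DataFrame with columns ``concentration, rate_mean, rate_se``.

    Returns a list of :class:`IndexEstimate` (plus a per-draw parameter
    DataFrame when ``return_draws``).
    """
    conc, means, ses = _coerce_rate_table(rate_estimates)
    if len(np.unique(conc)) < 4:
        raise ValueError("need valid rate estimates at >= 4 concentrations")
    if not np.any(np.isclose(conc, 0.0)):
        raise ValueError("a zero-concentration (control) rate estimate is required")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must lie in (0, 1)")
    i0 = int(np.argmin(conc))

    rules = _index_rules(index_specs, viability, t, n0_ratio)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {name: [] for name, _ in rules}
    failed: dict[str, int] = {name: 0 for name, _ in rules}
    params = []

    for _ in range(n_sims):
        sampled = rng.normal(means, ses)
        fit = fit_shifted_exponential(conc, sampled)
        if not fit.converged:
            for name, _ in rules:
                failed[name] += 1
            continue
        params.append((fit.amplitude, fit.decay, fit.floor))
        r0_draw = float(sampled[i0])
        for name, rule in rules:
            try:
                draws[name].append(invert_concentration(fit, rule(r0_draw)))
            except ValueError:
                failed[name] += 1

    # reference targets at the point-estimate control rate, for reporting
    r0_point = float(means[i0])
    alpha = 1.0 - conf_level
    out = []
    for name, rule in rules:
        vals = np.asarray(draws[name], dtype=float)
        n_failed = failed[name]
        if vals.size == 0:
            out.append(IndexEstimate(name, rule(r0_point), math.nan, math.nan,
                                     math.nan, vals, n_sims, n_failed, False,
                                     "all Monte-Carlo draws failed"))
            continue
        mean = float(vals.mean())
        if ci_method == "percentile":
            lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        elif ci_method == "normal":
            z = stats.norm.ppf(1.0 - alpha / 2.0)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            lo, hi = mean - z * sd, mean + z * sd
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        frac_failed = n_failed / n_sims
        valid = frac_failed < max_failed_fraction
        msg = "" if valid else (
            f"{frac_failed:.0%} of draws failed to fit or invert; "
            "estimate unreliable (check dose range and rate uncertainties)")
        out.append(IndexEstimate(name, rule(r0_point), mean, float(lo), float(hi),
                                 vals, n_sims, n_failed, valid, msg))
    if return_draws:
        return out, pd.DataFrame(params, columns=["amplitude", "decay", "floor"])
    return out


class ShiftedExponentialDoseResponse(RegressorMixin, BaseEstimator):
    """Scikit-learn-style regressor for the shifted-exponential model.

    ``fit(X, y)`` takes concentrations ``X`` (shape (n,) or (n, 1)) and
    growth rates ``y`` (days^-1); fitted parameters are exposed as
    ``amplitude_``, ``decay_``, ``floor_`` with ``rss_`` and ``converged_``.
    ``predict`` evaluates r(C); ``invert`` maps a target rate back to a
    concentration.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).reshape(-1)
        r = np.asarray(y, dtype=float).reshape(-1)
        fit = fit_shifted_exponential(c, r, maxfev=self.maxfev)
        self.fit_ = fit
        self.amplitude_ = fit.amplitude
        self.decay_ = fit.decay
        self.floor_ = fit.floor
        self.rss_ = fit.rss
        self.converged_ = fit.converged
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.fit_.predict(c)

    def invert(self, target_rate: float) -> float:
        return invert_concentration(self.fit_, target_rate)


class MonteCarloIndexEstimator(BaseEstimator):
    """Estimator wrapper around :func:`monte_carlo_indices`.

    ``fit`` accepts a rate table (DataFrame with ``concentration, rate_mean,
    rate_se`` or a list of :class:`GrowthRateEstimate`); results land in
    ``indices_`` (list of :class:`IndexEstimate`) and ``summary_``
    (DataFrame, one row per index).
    """

    def __init__(self, indices=("IC50", "ICr0", "ICrmed"), n_sims: int = 1000,
                 conf_level: float = 0.90, viability: float = 0.5,
                 t: float = 3.0, n0_ratio: float = 1.0,
                 ci_method: str = "percentile", random_state: int | None = None):
        self.indices = indices
        self.n_sims = n_sims
        self.conf_level = conf_level
        self.viability = viability
        self.t = t
        self.n0_ratio = n0_ratio
        self.ci_method = ci_method
        self.random_state = random_state

    def fit(self, X, y=None):
        self.indices_ = monte_carlo_indices(
            X, index_specs=self.indices, n_sims=self.n_sims,
            seed=self.random_state, conf_level=self.conf_level,
            viability=self.viability, t=self.t, n0_ratio=self.n0_ratio,
            ci_method=self.ci_method)
        self.summary_ = pd.DataFrame([
            {"index_name": e.index_name, "mean": e.mean, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "target_rate": e.target_rate,
             "n_sims": e.n_sims, "n_failed": e.n_failed, "valid": e.valid}
            for e in self.indices_])
        return self


def analyze_assay(assay: AssayTable, *, endpoints: Sequence[float] | None = None,
                  method: str = "paired", n_boot: int = 1000, n_sims: int = 1000,
                  seed: int | None = None, conf_level: float = 0.90,
                  viability: float = 0.5, t: float = 3.0, n0_ratio: float = 1.0,
                  include_t0: bool = True, pool_experiments: bool = True,
                  index_specs=("IC50", "ICr0", "ICrmed"),
                  ci_method: str = "percentile"):
    """Full pipeline: growth rates per concentration, then MC indices.

    ``endpoints`` (days) optionally restricts the observation times used for
    the growth-rate fits — e.g. ``(0, 3)`` reproduces the reduced 0 h + 72 h
    design. Returns ``(rate_estimates, index_estimates)``.
    """
    if endpoints is not None:
        endpoints = sorted(float(e) for e in endpoints)
        if not np.isclose(endpoints[0], 0.0) or len(endpoints) < 2:
            raise ValueError("endpoints must include 0 (seeding time) and at least one later time")
        assay = assay.subset_times(endpoints)
    rate_seed, mc_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2))
    rates = estimate_growth_rates(assay, method=method, n_boot=n_boot,
                                  seed=rate_seed, conf_level=conf_level,
                                  include_t0=include_t0,
                                  pool_experiments=pool_experiments)
    indices = monte_carlo_indices(rates, index_specs=index_specs, n_sims=n_sims,
                                  seed=mc_seed, conf_level=conf_level,
                                  viability=viability, t=t, n0_ratio=n0_ratio,
                                  ci_method=ci_method)
    return rates, indices


def reduced_endpoint_indices(assay: AssayTable, endpoints: Sequence[float],
                             **kwargs) -> list[IndexEstimate]:
    """Indices from a restricted set of observation times (days).

    ``endpoints`` must include the seeding time 0 and at least one later
    observed time; with only {0, 3} days the growth rate comes from a
    two-point-per-replicate fit, mirroring the reduced 0 h + 72 h design.
    """
    _, indices = analyze_assay(assay, endpoints=endpoints, **kwargs)
    return indices
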