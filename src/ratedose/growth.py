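"""Effective growth-rate estimation by log-linear fits with bootstrap CIs.

Under Malthusian growth N(t) = N0·e^{r·t}, the log of the t0-normalized
absorbance is linear in time with slope r, the effective growth rate
(days^-1). The slope is estimated by ordinary least squares; its sampling
distribution is obtained by resampling — either the empirical (paired)
bootstrap of (time, log-absorbance) pairs or the residual bootstrap with
fixed design points — and summarized as a normal-approximation confidence
interval r̄ ± z_{α/2}·SE (a percentile interval is available).

Two diagnostics guard the model assumptions: an exponential-growth check on
the R² of the log-linear fit, and a moment-based normality check of the
bootstrap slope distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .assay_io import AssayTable, NormalizedSeries, normalize_to_t0

__all__ = [
    "GrowthRateEstimate",
    "GrowthRateEstimator",
    "fit_log_linear",
    "bootstrap_rate",
    "check_exponential",
    "check_normality",
    "estimate_growth_rates",
]


@dataclass
class GrowthRateEstimate:
    """Bootstrap summary of one concentration's effective growth rate."""

    concentration: float
    rate_mean: float          # mean of bootstrap slopes, days^-1
    rate_se: float            # SD of bootstrap slopes
    ci_low: float
    ci_high: float
    bootstrap_slopes: np.ndarray
    intercept_mean: float
    r_squared: float          # of the base (non-resampled) fit
    exponential_ok: bool
    normality_ok: bool

    @property
    def n_boot(self) -> int:
        return len(self.bootstrap_slopes)


def _as_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, NormalizedSeries):
        return series.times, series.log_values
    t, y = series
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def fit_log_linear(series) -> tuple[float, float, float]:
    """OLS fit of log-values vs. time.

    Accepts a :class:`NormalizedSeries` or a ``(times, log_values)`` pair.
    Returns ``(slope, intercept, r_squared)`` with slope in days^-1.
    A constant series has slope 0 and, since the fit is exact, R² = 1.
    """
    t, y = _as_arrays(series)
    if len(np.unique(t)) < 2:
        raise ValueError("all times identical: slope is undefined")
    if t.size < 3:
        raise ValueError("need at least 3 observations for a growth-rate fit")
    tbar, ybar = t.mean(), y.mean()
    tc = t - tbar
    denom = np.dot(tc, tc)
    slope = float(np.dot(tc, y - ybar) / denom)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    tss = float(np.dot(y - ybar, y - ybar))
    rss = float(np.dot(resid, resid))
    r_squared = 1.0 if tss == 0.0 else 1.0 - rss / tss
    return slope, intercept, max(0.0, r_squared)


def _slopes_intercepts(tb: np.ndarray, yb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slopes/intercepts for resampled design matrices."""
    tm = tb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    tc = tb - tm
    slopes = np.einsum("ij,ij->i", tc, yb - ym) / np.einsum("ij,ij->i", tc, tc)
    intercepts = ym[:, 0] - slopes * tm[:, 0]
    return slopes, intercepts


def bootstrap_rate(series, method: str = "paired", n_boot: int = 1000,
                   seed: int | None = None, conf_level: float = 0.90,
                   ci_method: str = "normal", r2_threshold: float = 0.90,
                   flatness_floor: float = 0.1) -> GrowthRateEstimate:
    """Bootstrap the growth-rate slope of one normalized series.

    Parameters
    ----------
    series
        :class:`NormalizedSeries` or ``(times, log_values)``.
    method
        ``"paired"`` resamples (time, log-value) pairs with replacement;
        ``"residual"`` keeps the design fixed and resamples fit residuals.
    n_boot
        Number of bootstrap samples (1000 by default).
    seed
        Seed for reproducibility; identical seeds give identical draws.
    conf_level
        Two-sided confidence level of the interval (default 0.90).
    ci_method
        ``"normal"``: r̄ ± z_{α/2}·SE. ``"percentile"``: empirical quantiles
        of the bootstrap slope distribution.

    Paired resamples that collapse onto a single time point cannot be fitted
    and are redrawn, up to ``10 * n_boot`` redraws in total.
    """
    t, y = _as_arrays(series)
    slope0, intercept0, r_squared = fit_log_linear((t, y))
    rng = np.random.default_rng(seed)
    n = t.size

    if method == "paired":
        idx = rng.integers(0, n, size=(n_boot, n))
        tb, yb = t[idx], y[idx]
        degenerate = np.all(tb == tb[:, :1], axis=1)
        redraws = 0
        while degenerate.any():
            redraws += int(degenerate.sum())
            if redraws > 10 * n_boot:
                raise RuntimeError(
                    "paired bootstrap: too many degenerate resamples "
                    "(single time point); data are too sparse")
            idx = rng.integers(0, n, size=(int(degenerate.sum()), n))
            tb[degenerate], yb[degenerate] = t[idx], y[idx]
            degenerate2 = np.all(tb == tb[:, :1], axis=1)
            degenerate = degenerate2
    elif method == "residual":
        fitted = intercept0 + slope0 * t
        resid = y - fitted
        eb = resid[rng.integers(0, n, size=(n_boot, n))]
        tb = np.broadcast_to(t, (n_boot, n))
        yb = fitted + eb
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    slopes, intercepts = _slopes_intercepts(tb, yb)
    rate_mean = float(slopes.mean())
    rate_se = float(slopes.std(ddof=1)) if n_boot > 1 else 0.0

    alpha = 1.0 - conf_level
    if ci_method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_low, ci_high = rate_mean - z * rate_se, rate_mean + z * rate_se
    elif ci_method == "percentile":
        ci_low, ci_high = np.quantile(slopes, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    exp_ok, _ = check_exponential((t, y), r2_threshold=r2_threshold,
                                  flatness_floor=flatness_floor)
    norm_ok = check_normality(slopes) if n_boot >= 100 else True
    conc = series.concentration if isinstance(series, NormalizedSeries) else float("nan")
    return GrowthRateEstimate(
        concentration=conc, rate_mean=rate_mean, rate_se=rate_se,
        ci_low=float(ci_low), ci_high=float(ci_high),
        bootstrap_slopes=slopes, intercept_mean=float(intercepts.mean()),
        r_squared=r_squared, exponential_ok=exp_ok, normality_ok=norm_ok)


def check_exponential(series, r2_threshold: float = 0.90,
                      flatness_floor: float = 0.1) -> tuple[bool, float]:
    """Verify that a series is consistent with exponential growth/decline.

    When the fitted log-change over the observation window exceeds
    ``flatness_floor`` (|slope|·Δt > 0.1 by default), the check is the R² of
    the log-linear fit against ``r2_threshold``. Near zero growth R² is
    uninformative (a flat noisy series has R² ≈ 0 yet is perfectly
    exponential with r ≈ 0), so flat series are instead rejected only when a
    quadratic time term absorbs more than half of the linear fit's residual
    variance — i.e. when there is systematic curvature, not mere noise.
    """
    t, y = _as_arrays(series)
    slope, intercept, r_squared = fit_log_linear((t, y))
    span = t.max() - t.min()
    if abs(slope) * span > flatness_floor:
        return bool(r_squared >= r2_threshold), r_squared
    # flat regime: curvature test
    resid = y - (intercept + slope * t)
    rss_lin = float(np.dot(resid, resid))
    if rss_lin == 0.0 or len(np.unique(t)) < 3:
        return True, r_squared
    coeffs = np.polyfit(t, y, 2)
    resid2 = y - np.polyval(coeffs, t)
    rss_quad = float(np.dot(resid2, resid2))
    curvature_gain = 1.0 - rss_quad / rss_lin
    return bool(curvature_gain <= 0.5), r_squared


def check_normality(bootstrap_slopes: np.ndarray,
                    max_abs_skew: float = 0.5,
                    max_abs_excess_kurtosis: float = 1.0) -> bool:
    """Moment-based normality screen of the bootstrap slope distribution.

    With ~1000 bootstrap replicates a formal test (Shapiro, Anderson-Darling)
    rejects for trivially small departures, so the screen instead requires
    |skewness| < 0.5 and |excess kurtosis| < 1 — departures small enough that
    the normal-approximation CI is trustworthy.
    """
    slopes = np.asarray(bootstrap_slopes, dtype=float)
    if slopes.size < 100:
        raise ValueError("need at least 100 bootstrap slopes for the normality screen")
    if np.allclose(slopes, slopes[0]):
        return True  # degenerate (noise-free) distribution: nothing to reject
    skew = stats.skew(slopes)
    ex_kurt = stats.kurtosis(slopes)  # Fisher: normal -> 0
    return bool(abs(skew) < max_abs_skew and abs(ex_kurt) < max_abs_excess_kurtosis)


class GrowthRateEstimator(BaseEstimator):
    """Scikit-learn-style estimator for one series' effective growth rate.

    Parameters
    ----------
    method : {"paired", "residual"}
        Bootstrap flavour (empirical pair resampling vs. fixed-design
        residual resampling).
    n_boot : int
        Bootstrap replicates.
    conf_level : float
        Two-sided confidence level.
    ci_method : {"normal", "percentile"}
    r2_threshold, flatness_floor : float
        Exponentiality-check tuning (see :func:`check_exponential`).
    random_state : int or None

    Attributes (after :meth:`fit`)
    ------------------------------
    rate_ : float
        Mean bootstrap slope (days^-1).
    rate_se_, ci_low_, ci_high_, intercept_, r_squared_ : float
    bootstrap_slopes_ : ndarray of shape (n_boot,)
    exponential_ok_, normality_ok_ : bool
    """

    def __init__(self, method: str = "paired", n_boot: int = 1000,
                 conf_level: float = 0.90, ci_method: str = "normal",
                 r2_threshold: float = 0.90, flatness_floor: float = 0.1,
                 random_state: int | None = None):
        self.method = method
        self.n_boot = n_boot
        self.conf_level = conf_level
        self.ci_method = ci_method
        self.r2_threshold = r2_threshold
        self.flatness_floor = flatness_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit to times ``X`` (shape (n,) or (n, 1), days) and log-values ``y``,
        or to a single :class:`NormalizedSeries` passed as ``X``."""
        if isinstance(X, NormalizedSeries):
            series = X
        else:
            t = np.asarray(X, dtype=float).reshape(-1)
            series = (t, np.asarray(y, dtype=float).reshape(-1))
        est = bootstrap_rate(series, method=self.method, n_boot=self.n_boot,
                             seed=self.random_state, conf_level=self.conf_level,
                             ci_method=self.ci_method,
                             r2_threshold=self.r2_threshold,
                             flatness_floor=self.flatness_floor)
        self.estimate_ = est
        self.rate_ = est.rate_mean
        self.rate_se_ = est.rate_se
        self.ci_low_, self.ci_high_ = est.ci_low, est.ci_high
        self.intercept_ = est.intercept_mean
        self.r_squared_ = est.r_squared
        self.bootstrap_slopes_ = est.bootstrap_slopes
        self.exponential_ok_ = est.exponential_ok
        self.normality_ok_ = est.normality_ok
        return self

    def predict(self, X):
        """Predicted log-values at times ``X`` from the mean fit."""
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.rate_ * t


def estimate_growth_rates(assay: AssayTable, *, method: str = "paired",
                          n_boot: int = 1000, seed: int | None = None,
                          conf_level: float = 0.90, ci_method: str = "normal",
                          r2_threshold: float = 0.90, include_t0: bool = True,
                          pool_experiments: bool = True) -> list[GrowthRateEstimate]:
    """Estimate growth rates for every concentration of an assay.

    Per-concentration sub-seeds are spawned deterministically from ``seed``
    so the whole table is reproducible from one master seed. With
    ``include_t0=False`` the t=0 observations are dropped from the fit
    (they still define the normalization). With ``pool_experiments=False``
    each experiment is fitted separately and the per-experiment bootstrap
    slope distributions are concatenated before summarizing.
    """
    concs = assay.concentrations
    children = np.random.SeedSequence(seed).spawn(len(concs))
    estimates = []
    for conc, ss in zip(concs, children):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        if pool_experiments:
            series = normalize_to_t0(assay, conc)
            if not include_t0:
                keep = ~np.isclose(series.times, 0.0)
                series = NormalizedSeries(conc, series.times[keep], series.log_values[keep])
            est = bootstrap_rate(series, method=method, n_boot=n_boot,
                                 seed=sub_seed, conf_level=conf_level,
                                 ci_method=ci_method, r2_threshold=r2_threshold)
        else:
            est = _per_experiment_estimate(assay, conc, method, n_boot, sub_seed,
                                           conf_level, ci_method, r2_threshold,
                                           include_t0)
        estimates.append(est)
    return estimates


def _per_experiment_estimate(assay, conc, method, n_boot, seed, conf_level,
                             ci_method, r2_threshold, include_t0) -> GrowthRateEstimate:
    df = assay.data
    mask = np.isclose(df["concentration"].to_numpy(), conc)
    experiments = sorted(df[mask]["experiment"].unique())
    sub = AssayTable(df[mask | np.isclose(df["concentration"].to_numpy(), 0.0)].copy(),
                     assay.drug_name, assay.cell_line, assay.concentration_unit)
    all_slopes, r2s, intercepts = [], [], []
    exp_ok_all, norm_ok_all = True, True
    children = np.random.SeedSequence(seed).spawn(len(experiments))
    for exp_id, ss in zip(experiments, children):
        exp_rows = sub.data[sub.data["experiment"] == exp_id]
        one = AssayTable(exp_rows.copy(), assay.drug_name, assay.cell_line,
                         assay.concentration_unit)
        series = normalize_to_t0(one, conc)
        if not include_t0:
            keep = ~np.isclose(series.times, 0.0)
            series = NormalizedSeries(conc, series.times[keep], series.log_values[keep])
        est = bootstrap_rate(series, method=method, n_boot=n_boot,
                             seed=int(ss.generate_state(1)[0] % (2**31)),
                             conf_level=conf_level, ci_method=ci_method,
                             r2_threshold=r2_threshold)
        all_slopes.append(est.bootstrap_slopes)
        r2s.append(est.r_squared)
        intercepts.append(est.intercept_mean)
        exp_ok_all &= est.exponential_ok
        norm_ok_all &= est.normality_ok
    slopes = np.concatenate(all_slopes)
    rate_mean = float(slopes.mean())
    rate_se = float(slopes.std(ddof=1))
    alpha = 1.0 - conf_level
    if ci_method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = rate_mean - z * rate_se, rate_mean + z * rate_se
    else:
        lo, hi = np.quantile(slopes, [alpha / 2.0, 1.0 - alpha / 2.0])
    return GrowthRateEstimate(
        concentration=float(conc), rate_mean=rate_mean, rate_se=rate_se,
        ci_low=float(lo), ci_high=float(hi), bootstrap_slopes=slopes,
        intercept_mean=float(np.mean(intercepts)), r_squared=float(np.mean(r2s)),
        exponential_ok=exp_ok_all, normality_ok=norm_ok_all)
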