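"""Endpoint viability and the conventional 4PL relative IC50 baseline.

Viability at an endpoint is the ratio of treated to control absorbance at
the same time, V(C, t) = A_C(t)/A_0(t) × 100 %. Because treated and control
populations grow at different rates, V depends explicitly on the endpoint:
V(t) = (N0C/N0*)·e^{(rC - r0)·t}. The conventional relative IC50 is the
midpoint of a four-parameter logistic (4PL) fit,

    Y = Ymin + (Ymax - Ymin) / (1 + (X / IC50)^H),

and inherits that time dependence — the property the growth-rate indices
are designed to remove.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .assay_io import AssayTable

__all__ = ["ViabilityPoint", "FourPLFit", "FourPL", "compute_viability", "fit_four_pl"]


@dataclass
class ViabilityPoint:
    concentration: float
    time: float            # days
    viability_pct: float   # can exceed 100


@dataclass
class FourPLFit:
    """Fitted 4PL parameters; ``ic50`` is the curve midpoint (relative IC50)."""

    y_min: float
    y_max: float
    hill: float
    ic50: float
    converged: bool
    ic50_in_range: bool = True

    def predict(self, concentrations) -> np.ndarray:
        x = np.asarray(concentrations, dtype=float)
        return _fourpl(x, self.y_min, self.y_max, self.hill, self.ic50)


def compute_viability(assay: AssayTable, time: float,
                      atol: float = 1e-9) -> list[ViabilityPoint]:
    """Per-concentration viability (%) at one observed time point.

    Mean treated absorbance divided by mean control (C=0) absorbance at the
    same time, ×100; the control is therefore 100 % by construction.
    """
    if time <= 0:
        raise ValueError("viability is defined at a positive endpoint time")
    df = assay.data
    tmask = np.isclose(df["time"].to_numpy(), time, atol=atol)
    at_t = df[tmask]
    control = at_t[np.isclose(at_t["concentration"].to_numpy(), 0.0)]
    if control.empty:
        raise ValueError(f"no control reading at t={time} days")
    ref = float(control["absorbance"].mean())
    points = []
    for conc in assay.concentrations:
        sel = at_t[np.isclose(at_t["concentration"].to_numpy(), conc)]
        if sel.empty:
            raise ValueError(f"time {time} days missing for concentration {conc}")
        points.append(ViabilityPoint(float(conc), float(time),
                                     float(sel["absorbance"].mean()) / ref * 100.0))
    return points


def _fourpl(x, y_min, y_max, hill, ic50):
    return y_min + (y_max - y_min) / (1.0 + (x / ic50) ** hill)


def fit_four_pl(viability_points, maxfev: int = 20000) -> FourPLFit:
    """Nonlinear least squares of the 4PL sigmoid to viability data.

    ``viability_points`` is a list of :class:`ViabilityPoint` or a
    ``(concentrations, viability_pct)`` pair. The C=0 control anchors the
    top of the curve but has no position on a log-dose axis; it is mapped to
    the smallest positive tested concentration / 100 for the fit. For
    decreasing-viability data a fit with Hill slope H <= 0 (or no decline at
    all) is marked non-converged.
    """
    if isinstance(viability_points, (list, tuple)) and viability_points and \
            isinstance(viability_points[0], ViabilityPoint):
        x = np.array([p.concentration for p in viability_points], dtype=float)
        y = np.array([p.viability_pct for p in viability_points], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in viability_points)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct concentrations for a 4PL fit")

    pos = x[x > 0]
    x_fit = np.where(x > 0, x, pos.min() / 100.0)

    y_min0, y_max0 = float(y.min()), float(y.max())
    mid = 0.5 * (y_min0 + y_max0)
    ic50_0 = float(x_fit[np.argmin(np.abs(y - mid))])
    ic50_0 = min(max(ic50_0, pos.min()), pos.max())
    p0 = [y_min0, y_max0, 1.0, ic50_0]
    lower = [-np.inf, -np.inf, -np.inf, 1e-12]
    upper = [np.inf, np.inf, np.inf, np.inf]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_fourpl, x_fit, y, p0=p0,
                                         bounds=(lower, upper), maxfev=maxfev)
    except (RuntimeError, ValueError):
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, False, False)

    y_min, y_max, hill, ic50 = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x_fit, y)[0, 1]
    decreasing = bool(corr < 0)  # nan (flat data) counts as non-decreasing
    converged = (np.isfinite(popt).all() and y_min < y_max and ic50 > 0
                 and not (decreasing and hill <= 0))
    in_range = bool(pos.min() <= ic50 <= pos.max())
    return FourPLFit(y_min, y_max, hill, ic50, bool(converged), in_range)


class FourPL(RegressorMixin, BaseEstimator):
    """Scikit-learn-style 4PL regressor.

    ``fit(X, y)`` takes concentrations (shape (n,) or (n, 1)) and viability
    percentages; parameters land in ``y_min_``, ``y_max_``, ``hill_``,
    ``ic50_``, with ``converged_`` and ``ic50_in_range_`` flags.
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        fit = fit_four_pl((x, np.asarray(y, dtype=float).reshape(-1)),
                          maxfev=self.maxfev)
        self.fit_ = fit
        self.y_min_ = fit.y_min
        self.y_max_ = fit.y_max
        self.hill_ = fit.hill
        self.ic50_ = fit.ic50
        self.converged_ = fit.converged
        self.ic50_in_range_ = fit.ic50_in_range
        return self

    def predict(self, X):
        return self.fit_.predict(np.asarray(X, dtype=float).reshape(-1))
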