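"""Synthetic plate assays with known ground truth.

The generator emulates the standard MTT design this package analyzes: a
96-well plate read at 0/24/48/72 h, three technical replicates per condition
in each of three independent experiments, and a two-fold dilution series
with a zero-concentration control. Each well grows exponentially,
N(t) = N0·e^{r(C)·t}, with the true rate following the shifted exponential
r(C) = A·e^{-decay·C} - floor; measurement noise is multiplicative
log-normal on absorbance (keeping absorbance positive and log-space
residuals homoscedastic), with an additive option for robustness checks.

Because the generating parameters are known, closed-form index values are
available as an oracle (:func:`ground_truth_indices`).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .assay_io import AssayTable

__all__ = ["SyntheticSpec", "generate_assay", "ground_truth_rate", "ground_truth_indices"]


def _default_concentrations() -> list[float]:
    # 11 points: control + ten 1:2 dilutions from 50 down (Table-1-style design)
    return [0.0] + [50.0 / 2 ** k for k in range(9, -1, -1)]


class SyntheticSpec(BaseModel):
    """Ground-truth description of a synthetic assay.

    Defaults mirror the canonical design: times {0, 1, 2, 3} days, 3
    technical replicates × 3 independent experiments, 11 concentrations
    (control + ten two-fold dilutions from 50), dose-response parameters
    (A, decay, floor) = (0.85, 0.06, 0.55) giving a control rate of
    0.30 days^-1, and log-normal noise sigma = 0.08.
    """

    amplitude: float = 0.85          # A, days^-1
    decay: float = 0.06              # per concentration unit
    floor: float = 0.55              # r_inf magnitude, days^-1
    concentrations: list[float] = Field(default_factory=_default_concentrations)
    times: list[float] = Field(default_factory=lambda: [0.0, 1.0, 2.0, 3.0])  # days
    n_experiments: int = 3
    n_replicates: int = 3
    noise_sigma: float = 0.08        # SD of log-normal multiplicative noise
    noise_model: str = "lognormal"   # or "additive"
    baseline_absorbance: float = 0.2
    seed: int = 0
    drug: str = "synthetic-drug"
    cell_line: str = "synthetic-line"
    concentration_unit: str = "ug/mL"

    @field_validator("concentrations")
    @classmethod
    def _has_control(cls, v):
        if not any(math.isclose(c, 0.0) for c in v):
            raise ValueError("concentrations must include the 0 control")
        if any(c < 0 for c in v):
            raise ValueError("concentrations must be non-negative")
        return v

    @field_validator("noise_sigma")
    @classmethod
    def _nonneg_sigma(cls, v):
        if v < 0:
            raise ValueError("noise_sigma must be non-negative")
        return v

    @field_validator("noise_model")
    @classmethod
    def _known_noise(cls, v):
        if v not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")
        return v

    @property
    def control_rate(self) -> float:
        """True growth rate at C=0: amplitude - floor."""
        return self.amplitude - self.floor


def ground_truth_rate(spec: SyntheticSpec, concentration) -> np.ndarray | float:
    """True effective growth rate(s) at the given concentration(s)."""
    c = np.asarray(concentration, dtype=float)
    r = spec.amplitude * np.exp(-spec.decay * c) - spec.floor
    return float(r) if r.ndim == 0 else r


def generate_assay(spec: SyntheticSpec) -> AssayTable:
    """Generate a tidy absorbance table from the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for conc in spec.concentrations:
        rate = ground_truth_rate(spec, conc)
        for exp in range(1, spec.n_experiments + 1):
            for rep in range(1, spec.n_replicates + 1):
                for t in spec.times:
                    clean = spec.baseline_absorbance * math.exp(rate * t)
                    if spec.noise_model == "lognormal":
                        absorbance = clean * math.exp(rng.normal(0.0, spec.noise_sigma))
                    else:
                        absorbance = clean + rng.normal(0.0, spec.noise_sigma * spec.baseline_absorbance)
                        absorbance = max(absorbance, 1e-6)
                    records.append({
                        "concentration": conc, "time": t,
                        "experiment": f"E{exp}", "replicate": f"R{rep}",
                        "absorbance": absorbance,
                    })
    return AssayTable(pd.DataFrame.from_records(records), drug_name=spec.drug,
                      cell_line=spec.cell_line,
                      concentration_unit=spec.concentration_unit)


def ground_truth_indices(spec: SyntheticSpec, v: float = 0.5,
                         t: float = 3.0) -> dict[str, float]:
    """Closed-form IC50/ICr0/ICrmed implied by the generating parameters.

    Inverts r(C) = A·e^{-decay·C} - floor at target rates r0 + ln(v)/t
    (IC50), 0 (ICr0) and r0/2 (ICrmed), where r0 = A - floor. Raises if a
    target lies outside the model's attainable range (-floor, r0].
    """
    r0 = spec.control_rate
    targets = {"IC50": r0 + math.log(v) / t, "ICr0": 0.0, "ICrmed": r0 / 2.0}
    out = {}
    for name, target in targets.items():
        if target <= -spec.floor:
            raise ValueError(f"{name}: target rate {target:g} at or below the floor; unreachable")
        if target > r0 + 1e-12:
            raise ValueError(f"{name}: target rate {target:g} above the control rate; "
                             "concentration would be negative")
        if math.isclose(target, r0, rel_tol=0, abs_tol=1e-12):
            out[name] = 0.0
        else:
            out[name] = -math.log((target + spec.floor) / spec.amplitude) / spec.decay
    return out
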