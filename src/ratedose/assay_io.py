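"""Reading, validation and normalization of plate-reader absorbance data.

The internal representation is tidy ("long") and uses days as the canonical
time unit, so that fitted growth rates come out in days^-1. Two input
dialects are supported:

* **long** — one CSV with columns ``cell_line, drug, concentration,
  conc_unit, time, time_unit, experiment, replicate, absorbance``;
* **wide** — a directory with one 96-well plate grid per time point
  (``t<hours>.csv``, rows A–H × columns 1–12) plus a ``layout.csv`` mapping
  wells to ``(concentration, experiment, replicate)``.

Absorbances must be blank-corrected upstream; no background subtraction is
performed here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayTable",
    "NormalizedSeries",
    "AssayValidationError",
    "read_assay_csv",
    "write_assay_csv",
    "write_plate_series",
    "normalize_to_t0",
]

#: multiplicative factors to convert a declared time unit into days
_TIME_FACTORS = {"h": 1.0 / 24.0, "hour": 1.0 / 24.0, "hours": 1.0 / 24.0,
                 "d": 1.0, "day": 1.0, "days": 1.0}

_LONG_REQUIRED = ("concentration", "time", "experiment", "replicate", "absorbance")


class AssayValidationError(ValueError):
    """Raised when an input table violates the assay-data contract."""


@dataclass
class AssayTable:
    """A validated, tidy table of absorbance observations.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``concentration`` (non-negative), ``time`` (days),
        ``experiment``, ``replicate``, ``absorbance`` (strictly positive),
        sorted by (concentration, time).
    drug_name, cell_line, concentration_unit : str
        Assay metadata carried through to outputs.
    """

    data: pd.DataFrame
    drug_name: str = ""
    cell_line: str = ""
    concentration_unit: str = "ug/mL"

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in _LONG_REQUIRED if c not in df.columns]
        if missing:
            raise AssayValidationError(f"missing required columns: {missing}")
        self.data = df.sort_values(["concentration", "time"], kind="stable").reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        bad = df.index[~(df["absorbance"] > 0)]
        if len(bad):
            raise AssayValidationError(
                f"non-positive absorbance at row(s) {list(bad[:5])}: "
                "log-transform is undefined; inputs must be blank-corrected and positive"
            )
        if (df["concentration"] < 0).any():
            raise AssayValidationError("negative concentrations are not allowed")
        if not np.isclose(df["concentration"].min(), 0.0):
            raise AssayValidationError(
                "no zero-concentration control series present; a C=0 control is mandatory"
            )
        for conc, grp in df.groupby("concentration"):
            times = np.sort(grp["time"].unique())
            if not np.isclose(times[0], 0.0):
                raise AssayValidationError(
                    f"concentration {conc}: no t=0 (seeding-time) reading; "
                    "normalization requires a t0 absorbance"
                )
            if len(times) < 2:
                raise AssayValidationError(
                    f"concentration {conc}: fewer than 2 distinct time points"
                )

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted unique concentrations, control (0) first."""
        return np.sort(self.data["concentration"].unique())

    @property
    def times(self) -> np.ndarray:
        """Sorted unique observation times in days."""
        return np.sort(self.data["time"].unique())

    def subset_times(self, times: Sequence[float], atol: float = 1e-9) -> "AssayTable":
        """Restrict to the given time points (days); all must be observed."""
        times = np.asarray(sorted(times), dtype=float)
        observed = self.times
        for t in times:
            if not np.any(np.isclose(observed, t, atol=atol)):
                raise AssayValidationError(f"time {t} days not observed in the assay")
        mask = np.zeros(len(self.data), dtype=bool)
        for t in times:
            mask |= np.isclose(self.data["time"].to_numpy(), t, atol=atol)
        return AssayTable(self.data[mask].copy(), self.drug_name, self.cell_line,
                          self.concentration_unit)


@dataclass
class NormalizedSeries:
    """One concentration series normalized to its seeding-time absorbance.

    ``times`` and ``log_values`` are observation-level (one entry per well
    reading), sorted by time; ``log_values`` are natural logs of absorbance
    divided by the per-experiment geometric-mean t0 absorbance, so the mean
    log-value at t=0 is exactly 0.
    """

    concentration: float
    times: np.ndarray
    log_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.times.shape != self.log_values.shape:
            raise ValueError("times and log_values must have equal length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.log_values = self.log_values[order]
        if len(np.unique(self.times)) < 2:
            raise AssayValidationError(
                f"concentration {self.concentration}: fewer than 2 distinct time points"
            )

    @property
    def distinct_times(self) -> np.ndarray:
        return np.unique(self.times)

    @property
    def n_replicates_per_time(self) -> list[int]:
        return [int(np.sum(self.times == t)) for t in self.distinct_times]


def _to_days(time: pd.Series, unit: pd.Series | str) -> pd.Series:
    if isinstance(unit, str):
        factors = _TIME_FACTORS.get(unit.strip().lower())
        if factors is None:
            raise AssayValidationError(f"unknown time unit {unit!r}")
        return time * factors
    lowered = unit.astype(str).str.strip().str.lower()
    unknown = sorted(set(lowered) - set(_TIME_FACTORS))
    if unknown:
        raise AssayValidationError(f"unknown time unit(s) {unknown}")
    return time * lowered.map(_TIME_FACTORS)


def read_assay_csv(path: str | Path, dialect: str = "long", *,
                   time_unit: str = "hours", cell_line: str = "",
                   drug: str = "", conc_unit: str = "ug/mL") -> AssayTable:
    """Read an assay into a validated :class:`AssayTable`.

    Parameters
    ----------
    path
        For the long dialect, a CSV file. For the wide dialect, a directory
        containing ``layout.csv`` and one ``t<hours>.csv`` plate grid per
        time point.
    dialect
        ``"long"`` or ``"wide"``.
    time_unit
        Default unit for the ``time`` column when the long CSV carries no
        ``time_unit`` column (wide plate files are always named in hours).
    cell_line, drug, conc_unit
        Metadata fallbacks; the long dialect's own columns win.
    """
    path = Path(path)
    if dialect == "long":
        return _read_long(path, time_unit, cell_line, drug, conc_unit)
    if dialect == "wide":
        return _read_wide(path, cell_line, drug, conc_unit)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def _read_long(path: Path, time_unit: str, cell_line: str, drug: str,
               conc_unit: str) -> AssayTable:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise AssayValidationError(f"{path}: missing required columns {missing}")
    unit = df["time_unit"] if "time_unit" in df.columns else time_unit
    tidy = pd.DataFrame({
        "concentration": pd.to_numeric(df["concentration"]),
        "time": _to_days(pd.to_numeric(df["time"]), unit),
        "experiment": df["experiment"],
        "replicate": df["replicate"],
        "absorbance": pd.to_numeric(df["absorbance"]),
    })
    meta = {
        "cell_line": str(df["cell_line"].iloc[0]) if "cell_line" in df.columns else cell_line,
        "drug": str(df["drug"].iloc[0]) if "drug" in df.columns else drug,
        "conc_unit": str(df["conc_unit"].iloc[0]) if "conc_unit" in df.columns else conc_unit,
    }
    return AssayTable(tidy, drug_name=meta["drug"], cell_line=meta["cell_line"],
                      concentration_unit=meta["conc_unit"])


_PLATE_FILE = re.compile(r"^t(?P<hours>\d+(?:\.\d+)?)\.csv$")


def _read_wide(directory: Path, cell_line: str, drug: str, conc_unit: str) -> AssayTable:
    if not directory.is_dir():
        raise FileNotFoundError(f"wide dialect expects a directory, got {directory}")
    layout_path = directory / "layout.csv"
    if not layout_path.exists():
        raise AssayValidationError(f"{directory}: layout.csv (well->condition map) is required")
    layout = pd.read_csv(layout_path)
    needed = {"well", "concentration", "experiment", "replicate"}
    if not needed.issubset(layout.columns):
        raise AssayValidationError(f"layout.csv must have columns {sorted(needed)}")
    layout = layout.set_index("well")

    records = []
    plate_files = sorted(p for p in directory.iterdir() if _PLATE_FILE.match(p.name))
    if not plate_files:
        raise AssayValidationError(f"{directory}: no plate files matching t<hours>.csv")
    for plate_path in plate_files:
        hours = float(_PLATE_FILE.match(plate_path.name).group("hours"))
        grid = pd.read_csv(plate_path, index_col=0)
        for row_label, row in grid.iterrows():
            for col_label, value in row.items():
                if pd.isna(value):
                    continue
                well = f"{row_label}{int(col_label)}"
                if well not in layout.index:
                    continue  # unused well
                cond = layout.loc[well]
                records.append({
                    "concentration": float(cond["concentration"]),
                    "time": hours / 24.0,
                    "experiment": cond["experiment"],
                    "replicate": cond["replicate"],
                    "absorbance": float(value),
                })
    tidy = pd.DataFrame.from_records(records)
    return AssayTable(tidy, drug_name=drug, cell_line=cell_line,
                      concentration_unit=conc_unit)


def write_assay_csv(assay: AssayTable, path: str | Path) -> None:
    """Write the long-CSV dialect (time in days, 12 significant digits)."""
    df = assay.data.copy()
    out = pd.DataFrame({
        "cell_line": assay.cell_line,
        "drug": assay.drug_name,
        "concentration": df["concentration"],
        "conc_unit": assay.concentration_unit,
        "time": df["time"],
        "time_unit": "days",
        "experiment": df["experiment"],
        "replicate": df["replicate"],
        "absorbance": df["absorbance"],
    })
    out.to_csv(path, index=False, float_format="%.12g")


def write_plate_series(assay: AssayTable, directory: str | Path) -> None:
    """Write the wide (96-well) dialect: one grid per time point + layout.csv.

    Conditions are assigned to wells row-major (A1, A2, ...); the assay must
    fit on one 96-well plate per time point.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conditions = (assay.data[["concentration", "experiment", "replicate"]]
                  .drop_duplicates().reset_index(drop=True))
    if len(conditions) > 96:
        raise ValueError("more than 96 conditions; cannot map onto one plate")
    rows = "ABCDEFGH"
    wells = [f"{rows[i // 12]}{i % 12 + 1}" for i in range(len(conditions))]
    conditions = conditions.assign(well=wells)
    conditions[["well", "concentration", "experiment", "replicate"]].to_csv(
        directory / "layout.csv", index=False, float_format="%.12g")

    keyed = assay.data.merge(conditions, on=["concentration", "experiment", "replicate"])
    for t, grp in keyed.groupby("time"):
        grid = pd.DataFrame(np.nan, index=list(rows), columns=[str(c) for c in range(1, 13)])
        for _, rec in grp.iterrows():
            well = rec["well"]
            grid.loc[well[0], well[1:]] = rec["absorbance"]
        hours = t * 24.0
        name = f"t{hours:g}.csv"
        grid.to_csv(directory / name, float_format="%.12g")


def normalize_to_t0(assay: AssayTable, concentration: float) -> NormalizedSeries:
    """Normalize one concentration series to its seeding-time absorbance.

    Each experiment is normalized independently: every absorbance in the
    experiment is divided by the geometric mean of that experiment's t=0
    absorbances, then natural-log-transformed. The geometric mean (arithmetic
    mean in log space) makes the t0 log-values average exactly to zero and is
    invariant to rescaling an experiment's absorbance units.
    """
    df = assay.data
    mask = np.isclose(df["concentration"].to_numpy(), concentration)
    if not mask.any():
        raise KeyError(f"concentration {concentration} not present in the assay")
    sub = df[mask]
    times, logs = [], []
    for _, grp in sub.groupby("experiment"):
        t = grp["time"].to_numpy(dtype=float)
        a = grp["absorbance"].to_numpy(dtype=float)
        at0 = a[np.isclose(t, 0.0)]
        if at0.size == 0:
            raise AssayValidationError(
                f"concentration {concentration}: an experiment lacks a t=0 reading")
        log_ref = float(np.mean(np.log(at0)))
        times.append(t)
        logs.append(np.log(a) - log_ref)
    return NormalizedSeries(concentration=float(concentration),
                            times=np.concatenate(times),
                            log_values=np.concatenate(logs))
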