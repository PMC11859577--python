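from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ratedose import AssayTable, SyntheticSpec, generate_assay

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"

#: printed per-concentration effective growth rates for the HCT116/oxaliplatin
#: worked example (growth rates in days^-1 with bootstrap standard errors)
HCT116_RATES = EXAMPLES / "hct116_oxaliplatin_rates.csv"


@pytest.fixture(scope="session")
def hct116_rates() -> pd.DataFrame:
    return pd.read_csv(HCT116_RATES)


@pytest.fixture()
def noise_free_assay() -> AssayTable:
    return generate_assay(SyntheticSpec(noise_sigma=0.0, seed=0))


@pytest.fixture()
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=42)


def make_long_csv(path: Path, *, concentrations=(0.0, 1.56), times_h=(0, 24, 48, 72),
                  n_reps=3, rate_fn=lambda c: 0.3 - 0.1 * c, baseline=0.2,
                  time_unit="hours") -> Path:
    """Write a minimal noise-free long-dialect assay CSV."""
    rows = []
    for c in concentrations:
        for t in times_h:
            for rep in range(1, n_reps + 1):
                rows.append({
                    "cell_line": "demo", "drug": "drugX", "concentration": c,
                    "conc_unit": "ug/mL", "time": t, "time_unit": time_unit,
                    "experiment": "E1", "replicate": f"R{rep}",
                    "absorbance": baseline * np.exp(rate_fn(c) * t / 24.0),
                })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
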