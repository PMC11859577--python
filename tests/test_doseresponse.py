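"""Shifted-exponential dose-response fitting, inversion and MC indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratedose import (DoseResponseFit, ShiftedExponentialDoseResponse,
                      fit_shifted_exponential, invert_concentration,
                      monte_carlo_indices, rate_for_viability,
                      reduced_endpoint_indices, analyze_assay,
                      SyntheticSpec, generate_assay)

TABLE_CONCS = np.array([0, 0.1, 0.2, 0.4, 0.8, 1.6, 3.13, 6.25, 12.5, 25, 50.0])


def test_exact_parameter_recovery():
    true = (0.85, 0.06, 0.55)
    rates = true[0] * np.exp(-true[1] * TABLE_CONCS) - true[2]
    fit = fit_shifted_exponential(TABLE_CONCS, rates)
    assert fit.converged
    for got, want in zip((fit.amplitude, fit.decay, fit.floor), true):
        assert got == pytest.approx(want, rel=1e-6)


def test_flat_rates_not_converged():
    fit = fit_shifted_exponential(TABLE_CONCS, np.full(11, 0.3))
    assert not fit.converged


def test_too_few_concentrations_raise():
    with pytest.raises(ValueError):
        fit_shifted_exponential([0, 1, 2], [0.3, 0.2, 0.1])
    with pytest.raises(ValueError):
        fit_shifted_exponential([1, 2, 4, 8], [0.3, 0.2, 0.1, 0.0])  # no control


def test_inversion_examples():
    fit = DoseResponseFit(amplitude=0.8, decay=0.1, floor=0.5, rss=0.0, converged=True)
    assert invert_concentration(fit, 0.8 - 0.5) == pytest.approx(0.0, abs=1e-9)
    c0 = invert_concentration(fit, 0.0)
    assert c0 == pytest.approx(10 * math.log(1.6), abs=1e-12)  # ~4.7004
    assert fit.predict(c0) == pytest.approx(0.0, abs=1e-12)    # forward check
    with pytest.raises(ValueError, match="floor"):
        invert_concentration(fit, -0.5)
    with pytest.raises(ValueError, match="not reached"):
        invert_concentration(fit, 0.31)
    with pytest.raises(ValueError):
        invert_concentration(DoseResponseFit(1, 1, 1, 0, False), 0.0)


@settings(deadline=None, max_examples=50)
@given(amplitude=st.floats(0.1, 2.0), decay=st.floats(0.01, 0.5),
       floor=st.floats(0.05, 1.0), frac=st.floats(1e-6, 1.0 - 1e-6))
def test_inversion_round_trip(amplitude, decay, floor, frac):
    """predict(invert(r)) == r to 1e-9 over the attainable rate range."""
    fit = DoseResponseFit(amplitude, decay, floor, 0.0, True)
    target = -floor + frac * amplitude  # in (-floor, rate_at_zero)
    c = invert_concentration(fit, target)
    assert c >= 0.0
    assert fit.predict(c) == pytest.approx(target, abs=1e-9)


def test_inversion_strictly_decreasing_in_target():
    fit = DoseResponseFit(0.85, 0.06, 0.55, 0.0, True)
    targets = np.linspace(-0.5, 0.29, 40)
    concs = [invert_concentration(fit, t) for t in targets]
    assert all(a > b for a, b in zip(concs, concs[1:]))


@pytest.mark.parametrize("r0, v, t, expected", [
    (0.30, 0.5, 3.0, 0.30 + math.log(0.5) / 3.0),   # the -0.2310 offset
    (0.70, 1.0, 2.0, 0.70),                          # V=1 identity
    (0.20, 0.25, 2.0, 0.20 + math.log(0.25) / 2.0),  # hand evaluation
])
def test_rate_for_viability(r0, v, t, expected):
    assert rate_for_viability(r0, v, t) == expected  # exact arithmetic


def test_rate_for_viability_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rate_for_viability(0.3, 0.0, 3.0)
    with pytest.raises(ValueError):
        rate_for_viability(0.3, 0.5, -1.0)


def test_monte_carlo_degenerate_zero_se():
    """With all SEs zero every draw is identical: point inversion, zero-width CI."""
    rates = 0.85 * np.exp(-0.06 * TABLE_CONCS) - 0.55
    table = pd.DataFrame({"concentration": TABLE_CONCS, "rate_mean": rates,
                          "rate_se": np.zeros(11)})
    ests = monte_carlo_indices(table, n_sims=200, seed=0)
    fit = fit_shifted_exponential(TABLE_CONCS, rates)
    by_name = {e.index_name: e for e in ests}
    r0 = rates[0]
    expected = {
        "IC50": invert_concentration(fit, r0 + math.log(0.5) / 3.0),
        "ICr0": invert_concentration(fit, 0.0),
        "ICrmed": invert_concentration(fit, r0 / 2.0),
    }
    for name, want in expected.items():
        e = by_name[name]
        assert e.mean == pytest.approx(want, rel=1e-6)
        assert e.ci_high - e.ci_low == pytest.approx(0.0, abs=1e-9)
        assert e.n_failed == 0


def test_worked_example_indices_and_ordering(hct116_rates):
    """The printed per-concentration rates yield indices inside the printed
    90% CIs, with the ordering ICrmed < IC50 < ICr0 (r0 = 0.30 < 0.462)."""
    ests = {e.index_name: e for e in
            monte_carlo_indices(hct116_rates, n_sims=1000, seed=20)}
    assert ests["IC50"].mean == pytest.approx(5.5, abs=1.0)
    assert ests["ICr0"].mean == pytest.approx(8.3, abs=1.5)
    assert ests["ICrmed"].mean == pytest.approx(2.9, abs=0.5)
    assert ests["ICrmed"].mean < ests["IC50"].mean < ests["ICr0"].mean
    for e in ests.values():
        assert e.valid and e.ci_low <= e.mean <= e.ci_high


def test_failed_draws_are_counted_not_resampled(hct116_rates):
    noisy = hct116_rates.assign(rate_se=hct116_rates.rate_se * 20)
    ests = monte_carlo_indices(noisy, n_sims=300, seed=1)
    assert any(e.n_failed > 0 for e in ests)
    for e in ests:
        assert len(e.mc_values) + e.n_failed == e.n_sims
        assert e.valid == (e.n_failed / e.n_sims < 0.2)


def test_reduced_endpoints_noise_free_match_full():
    assay = generate_assay(SyntheticSpec(noise_sigma=0.0, seed=0))
    full = {e.index_name: e.mean for e in
            reduced_endpoint_indices(assay, [0, 1, 2, 3], n_boot=200,
                                     n_sims=200, seed=5)}
    reduced = {e.index_name: e.mean for e in
               reduced_endpoint_indices(assay, [0, 3], n_boot=200,
                                        n_sims=200, seed=5)}
    for name in full:
        assert reduced[name] == pytest.approx(full[name], abs=1e-6)


def test_reduced_endpoints_require_t0(noise_free_assay):
    with pytest.raises(ValueError):
        reduced_endpoint_indices(noise_free_assay, [1.0])
    with pytest.raises(ValueError):
        reduced_endpoint_indices(noise_free_assay, [1.0, 3.0])


def test_noisy_reduced_endpoints_widen_cis():
    """Dropping the intermediate time points cannot sharpen the estimate."""
    wins = 0
    for seed in range(6):
        assay = generate_assay(SyntheticSpec(noise_sigma=0.08, seed=seed))
        _, full = analyze_assay(assay, n_boot=300, n_sims=300, seed=seed)
        _, red = analyze_assay(assay, endpoints=[0, 3], n_boot=300,
                               n_sims=300, seed=seed)
        f = {e.index_name: e.ci_high - e.ci_low for e in full}
        r = {e.index_name: e.ci_high - e.ci_low for e in red}
        wins += r["ICr0"] >= f["ICr0"]
    assert wins >= 4  # in most repeats


def test_sklearn_estimator_wrapper(hct116_rates):
    est = ShiftedExponentialDoseResponse().fit(
        hct116_rates.concentration, hct116_rates.rate_mean)
    assert est.converged_
    assert est.predict([0.0])[0] == pytest.approx(est.amplitude_ - est.floor_)
    c = est.invert(0.0)
    assert est.predict([c])[0] == pytest.approx(0.0, abs=1e-9)
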