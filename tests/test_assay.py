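"""Assay math: normalization, 4PL fitting, Cheng-Prusoff, EC-fraction."""

import numpy as np
import pytest

from focuslib.assay import (
    AssayConstants,
    binding_result,
    cheng_prusoff_ki,
    ec_fraction,
    fit_4pl,
    ic50_to_pic50,
    is_out_of_window,
    percent_displacement,
    percent_inhibition,
)
from focuslib.errors import ContractError, DegenerateWindowError
from focuslib.fixtures import FixtureSpec, four_pl, gen_curves


@pytest.mark.parametrize(
    "total, nsb, sample, expected",
    [
        (1000.0, 100.0, 1000.0, 0.0),
        (1000.0, 100.0, 100.0, 100.0),
        (1000.0, 100.0, 550.0, 50.0),
    ],
)
def test_percent_displacement(total, nsb, sample, expected):
    assert percent_displacement(total, nsb, sample) == pytest.approx(expected)


def test_percent_inhibition_endpoints_and_midpoint():
    assert percent_inhibition(2000.0, 500.0, 2000.0) == 0.0
    assert percent_inhibition(2000.0, 500.0, 500.0) == 100.0
    assert percent_inhibition(2000.0, 500.0, 1250.0) == 50.0


def test_degenerate_windows_raise():
    with pytest.raises(DegenerateWindowError):
        percent_displacement(100.0, 100.0, 50.0)
    with pytest.raises(DegenerateWindowError):
        percent_inhibition(100.0, 200.0, 50.0)


def test_percent_metrics_affine_invariant():
    base = percent_displacement(1000.0, 100.0, 400.0)
    shifted = percent_displacement(1500.0, 600.0, 900.0)
    assert base == pytest.approx(shifted)


def test_out_of_window_flag():
    assert is_out_of_window(percent_displacement(1000.0, 100.0, 50.0))
    assert not is_out_of_window(50.0)


def test_4pl_recovers_noiseless_curve():
    conc = np.logspace(-9, -3, 10)
    resp = four_pl(conc, 0.0, 100.0, 1.0, -6.0)
    fit = fit_4pl(conc, resp)
    assert fit.pic50 == pytest.approx(6.0, abs=1e-6)
    assert fit.hill == pytest.approx(1.0, abs=1e-6)
    assert fit.bottom <= fit.top


def test_4pl_decreasing_curve_orientation():
    conc = np.logspace(-9, -3, 10)
    resp = four_pl(conc, 100.0, 0.0, 1.0, -6.0)  # decreasing (inhibition)
    fit = fit_4pl(conc, resp)
    assert fit.bottom <= fit.top
    assert fit.pic50 == pytest.approx(6.0, abs=1e-5)


def test_4pl_contract_errors():
    with pytest.raises(ContractError):
        fit_4pl([1e-6, 1e-6, 1e-6, 1e-6], [1, 2, 3, 4])
    with pytest.raises(ContractError):
        fit_4pl([1e-7, 1e-6, 1e-5], [1, 2, 3])


def test_4pl_recovery_under_noise_seeded(tmp_path):
    """Median absolute pIC50 error stays < 0.2 at 5% noise, 8 points."""
    errors = []
    for i in range(100):
        spec = FixtureSpec(seed=1000 + i, curve_spec=(6.0, 1.0, 100.0, 0.0, 5.0, 8))
        truth = gen_curves(spec, tmp_path / f"curve_{i}.csv")
        import pandas as pd

        table = pd.read_csv(truth["path"])
        fit = fit_4pl(table["concentration_molar"], table["response"])
        errors.append(abs(fit.pic50 - 6.0))
    assert np.median(errors) < 0.2


def test_cheng_prusoff_closed_form():
    assert cheng_prusoff_ki(1e-6, 0.0, 6.3e-9) == pytest.approx(1e-6)
    ki = cheng_prusoff_ki(1000e-9, 6e-9, 6.3e-9)
    assert ki == pytest.approx(1000e-9 / (1 + 6 / 6.3), rel=1e-12)
    assert ki * 1e9 == pytest.approx(512.2, abs=0.1)


def test_cheng_prusoff_monotone_in_radioligand_conc():
    ki_values = [cheng_prusoff_ki(1e-6, c * 1e-9, 6.3e-9) for c in (0.0, 3.0, 6.0, 12.0)]
    assert all(a > b for a, b in zip(ki_values, ki_values[1:]))
    assert all(k <= 1e-6 for k in ki_values)


def test_cheng_prusoff_contract():
    with pytest.raises(ContractError):
        cheng_prusoff_ki(1e-6, 6e-9, 0.0)
    with pytest.raises(ContractError):
        cheng_prusoff_ki(-1e-6, 6e-9, 6.3e-9)


def test_ic50_to_pic50_printed_value():
    # a 10.79 micromolar IC50 corresponds to pIC50 4.97
    assert ic50_to_pic50(10.79e-6) == pytest.approx(4.97, abs=0.005)


def test_ec_fraction_identities():
    assert ec_fraction(5e-9, 1.0, 0.5) == pytest.approx(5e-9)
    assert ec_fraction(5e-9, 1.0, 0.8) == pytest.approx(4 * 5e-9)
    assert ec_fraction(5e-9, 2.0, 0.8) == pytest.approx(2 * 5e-9)
    with pytest.raises(ContractError):
        ec_fraction(5e-9, 0.0, 0.8)
    with pytest.raises(ContractError):
        ec_fraction(5e-9, 1.0, 1.0)


def test_binding_result_defaults_are_study_constants():
    constants = AssayConstants()
    assert constants.radioligand_conc_nm == pytest.approx(6.0)
    assert constants.radioligand_kd_nm == pytest.approx(6.3)
    result = binding_result(10e-6)
    assert result.ki_molar < result.ic50_molar
    assert result.pki == pytest.approx(-np.log10(result.ki_molar))
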