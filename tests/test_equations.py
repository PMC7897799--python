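"""Unit and property tests for the two-pool rCO2 equation family.

Expected values are frozen from direct-arithmetic oracles: each rCO2
variant is a product of printed constants, so the oracle is the explicit
product written out independently of the implementation's code path.
"""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dlwcalc import (
    ConfigurationError,
    DataError,
    IsotopeKinetics,
    KineticsError,
    NonPositiveProductionError,
    compute_rco2,
    pool_size_oxygen,
    pool_size_two_pool,
    rco2_adult,
    rco2_generic,
    rco2_infant,
    rco2_mass_dependent,
    rco2_preterm,
    select_equation,
)
from dlwcalc.constants import DEFAULT_CONSTANTS


def kin(ko=0.12, kd=0.10, No=2014.0, Nd=None, body_mass=None, **kw):
    return IsotopeKinetics("t", ko=ko, kd=kd, No=No, Nd=Nd,
                           body_mass=body_mass, **kw)


# ---------------------------------------------------------------------------
# pool-size conventions

@pytest.mark.parametrize("No, Nd, expected", [
    (2014.0, 2086.0, 2000.0),     # both terms constructed to equal 2000
    (1007.0, 1043.0, 1000.0),
])
def test_two_pool_average(No, Nd, expected):
    assert pool_size_two_pool(No, Nd) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("No, expected", [
    (2014.0, 2000.0), (1.007, 1.0), (1510.5, 1500.0),
])
def test_oxygen_only_pool(No, expected):
    assert pool_size_oxygen(No) == pytest.approx(expected, rel=1e-12)


def test_pool_domain_errors():
    with pytest.raises(DataError):
        pool_size_two_pool(-1.0, 2000.0)
    with pytest.raises(DataError):
        pool_size_oxygen(0.0)


def test_adult_falls_back_to_oxygen_pool_without_Nd():
    result = rco2_adult(kin(Nd=None))
    assert result.pool_convention == "oxygen_only"
    assert result.pool_size_used == pytest.approx(2000.0, rel=1e-12)


# ---------------------------------------------------------------------------
# the equation variants against direct-arithmetic oracles

def test_generic_equation_oracle():
    # 0.45859 * 2000 * (0.12 - 1.0*0.10) * 22.26
    assert rco2_generic(2000, 0.12, 0.10, 1.0) == pytest.approx(
        0.45859 * 2000 * 0.02 * 22.26, rel=1e-12)
    assert rco2_generic(2000, 0.12, 0.10, 1.0) == pytest.approx(408.3, abs=0.05)
    # DSR 1.036 subtracts more deuterium flux
    assert rco2_generic(2000, 0.12, 0.10, 1.036) == pytest.approx(
        0.45859 * 2000 * (0.12 - 1.036 * 0.10) * 22.26, rel=1e-12)
    assert rco2_generic(2000, 0.12, 0.10, 1.036) == pytest.approx(334.8, abs=0.05)


def test_generic_zero_production_is_structured_error():
    with pytest.raises(NonPositiveProductionError) as exc_info:
        rco2_generic(2000, 0.104, 0.10, 1.04)   # ko == dsr*kd
    assert exc_info.value.code == "non_positive_rco2"
    assert exc_info.value.context["kd"] == 0.10


def test_generic_rejects_unphysiological_dsr():
    with pytest.raises(DataError):
        rco2_generic(2000, 0.12, 0.10, 1.5)


def test_adult_equation_oracle():
    result = rco2_adult(kin(Nd=2086.0))
    # 0.4554 * 2000 * (1.007*0.12 - 1.043*0.10) * 22.26
    assert result.rco2 == pytest.approx(
        0.4554 * 2000 * (0.12084 - 0.1043) * 22.26, rel=1e-9)
    assert result.rco2 == pytest.approx(335.3, abs=0.05)
    assert result.equation_id == "adult"
    assert result.dsr_used == 1.036


def test_adult_zero_production_when_fluxes_cancel():
    with pytest.raises(NonPositiveProductionError):
        rco2_adult(kin(ko=1.043, kd=1.007, No=2014.0))   # 1.007*ko == 1.043*kd


def test_preterm_equation_oracle():
    result = rco2_preterm(kin(ko=0.30, kd=0.25, No=503.5))   # N = 500
    assert result.rco2 == pytest.approx(
        0.4554 * 500 * (0.3021 - 0.2565) * 22.26, rel=1e-9)
    assert result.rco2 == pytest.approx(231.1, abs=0.05)
    assert result.dsr_used == 1.019
    with pytest.raises(NonPositiveProductionError):
        rco2_preterm(kin(ko=1.026, kd=1.007, No=503.5))


def test_infant_equation_oracle():
    result = rco2_infant(kin(ko=0.30, kd=0.25, No=503.5))
    assert result.rco2 == pytest.approx(
        0.4554 * 500 * (0.3021 - 0.2595) * 22.26, rel=1e-9)
    assert result.rco2 == pytest.approx(215.9, abs=0.05)
    with pytest.raises(NonPositiveProductionError):
        rco2_infant(kin(ko=1.038, kd=1.007, No=503.5))


def test_dsr_ordering_of_variants():
    """Smaller population DSR subtracts less deuterium flux, so
    preterm > infant > adult for identical kinetics."""
    k = kin(ko=0.30, kd=0.25, No=503.5)
    preterm = rco2_preterm(k).rco2
    infant = rco2_infant(k).rco2
    adult = rco2_adult(k, pool_convention="oxygen_only").rco2
    assert preterm > infant > adult


def test_mass_dependent_oracle():
    # DSR(2.0) = 1.036 - 0.05*exp(-1.0498), then Eq-11 form on N = 500
    k = kin(ko=0.30, kd=0.25, No=503.5, body_mass=2.0)
    dsr = 1.036 - 0.05 * math.exp(-0.5249 * 2.0)
    expected = 0.45859 * 500 * (0.30 - dsr * 0.25) * 22.26
    result = rco2_mass_dependent(k)
    assert result.rco2 == pytest.approx(expected, rel=1e-9)
    assert result.rco2 == pytest.approx(231.6, abs=0.05)
    assert result.dsr_used == pytest.approx(dsr, rel=1e-12)
    assert result.equation_id == "mass_dependent"


def test_mass_dependent_matches_adult_at_large_mass():
    """At 20 kg the DSR curve is within 2e-6 of 1.036, so the
    mass-dependent result agrees with the adult oxygen-pool result."""
    k = kin(ko=0.12, kd=0.10, No=2014.0, body_mass=20.0)
    md = rco2_mass_dependent(k).rco2
    adult = rco2_adult(k, pool_convention="oxygen_only").rco2
    assert md == pytest.approx(adult, rel=5e-3)


def test_mass_dependent_requires_mass():
    with pytest.raises(ConfigurationError):
        rco2_mass_dependent(kin(body_mass=None))


def test_mass_dependent_literal_No_pool_option():
    k = kin(ko=0.30, kd=0.25, No=503.5, body_mass=2.0)
    default = rco2_mass_dependent(k).rco2
    literal = rco2_mass_dependent(k, literal_No_pool=True).rco2
    assert literal / default == pytest.approx(1.007, rel=1e-12)


# ---------------------------------------------------------------------------
# equation selection

@pytest.mark.parametrize("mass, expected", [
    (80.0, "adult"), (5.0, "mass_dependent"), (10.0, "adult"),
])
def test_select_equation(mass, expected):
    assert select_equation(mass) == expected


def test_select_equation_requires_mass():
    with pytest.raises(ConfigurationError):
        select_equation(None)


def test_compute_rco2_auto_dispatch():
    adult = compute_rco2(kin(Nd=2086.0, body_mass=80.0))
    assert adult.equation_id == "adult"
    baby = compute_rco2(kin(ko=0.30, kd=0.25, No=503.5, body_mass=2.0))
    assert baby.equation_id == "mass_dependent"
    with pytest.raises(ConfigurationError):
        compute_rco2(kin(), equation="generic")     # generic needs a DSR


# ---------------------------------------------------------------------------
# kinetics invariants

def test_ko_must_exceed_kd():
    with pytest.raises(KineticsError) as exc_info:
        IsotopeKinetics("x", ko=0.10, kd=0.12, No=2000.0)
    assert exc_info.value.code == "ko_le_kd"


def test_implausible_dsr_warns_or_fails():
    with pytest.warns(UserWarning):
        IsotopeKinetics("x", ko=0.12, kd=0.10, No=2000.0, Nd=2400.0)
    with pytest.raises(KineticsError):
        IsotopeKinetics("x", ko=0.12, kd=0.10, No=2000.0, Nd=2400.0,
                        strict_dsr=True)


# ---------------------------------------------------------------------------
# algebraic properties

grid = dict(
    ko=st.floats(min_value=0.05, max_value=0.5),
    # kd/ko capped at 1/1.15: the printed coefficients are rounded at the
    # fifth decimal, and the flux difference amplifies that rounding, so
    # the three forms agree to 1e-4 only on the physiological domain
    # ko/kd >= 1.15 (at kd/ko = 0.95 the discrepancy reaches ~6e-4)
    ratio=st.floats(min_value=0.6, max_value=0.869),
    N=st.floats(min_value=100.0, max_value=4000.0),
)


@given(**grid)
def test_long_and_simplified_forms_agree(ko, ratio, N):
    """The long fractionation-corrected form, the 0.4554 simplified form
    and the fully collapsed per-isotope form agree to 1e-4 relative
    wherever ko/kd >= 1.15."""
    kd = ko * ratio
    flux = 1.007 * ko - 1.043 * kd
    long_form = ((N / 2.078) * flux - 0.0246 * N * 1.05 * flux) * 22.26
    simplified = 0.4554 * N * flux * 22.26
    collapsed = N * (0.45859 * ko - 0.47498 * kd) * 22.26
    assert simplified == pytest.approx(long_form, rel=1e-4)
    assert collapsed == pytest.approx(long_form, rel=1e-4)
    assert rco2_adult(kin(ko=ko, kd=kd, No=N * 1.007)).rco2 == pytest.approx(
        long_form, rel=1e-4)


def test_printed_coefficients_consistent():
    assert round(1 / 2.078 - 0.0246 * 1.05, 5) == 0.45540
    assert round(0.4554 * 1.007, 5) == 0.45859
    assert round(0.4554 * 1.043, 5) == 0.47498
    assert DEFAULT_CONSTANTS.flux_coefficient == pytest.approx(0.4554, abs=5e-6)


@given(**grid, scale=st.floats(min_value=1.1, max_value=3.0))
def test_monotonicity_and_homogeneity(ko, ratio, N, scale):
    """rCO2 rises with ko and N, falls with kd and DSR, and is linear in N."""
    kd = ko * ratio
    if 0.12 - 1.05 * ratio <= 0:   # keep flux positive under the 1.05 DSR probe
        return
    base = rco2_generic(N, ko, kd, 1.0)
    assert rco2_generic(N, ko * scale, kd, 1.0) > base
    assert rco2_generic(N * scale, ko, kd, 1.0) == pytest.approx(
        base * scale, rel=1e-12)
    assert rco2_generic(N, ko, kd * 0.9, 1.0) > base
    if ko - 1.05 * kd > 0:
        assert rco2_generic(N, ko, kd, 1.05) < base


def test_legacy_gas_constant_bias_is_exact_ratio():
    """Using the ideal-gas 22.4 L/mol inflates rCO2 by exactly
    22.4/22.26 - 1 = 0.629% (quoted as ~0.7%)."""
    legacy = DEFAULT_CONSTANTS.replace(co2_molar_volume=22.4)
    standard = rco2_adult(kin(Nd=2086.0)).rco2
    inflated = rco2_adult(kin(Nd=2086.0), constants=legacy).rco2
    assert inflated / standard - 1 == pytest.approx(22.4 / 22.26 - 1, rel=1e-12)
    assert 100 * (22.4 / 22.26 - 1) == pytest.approx(0.629, abs=5e-4)


@given(ko=st.floats(min_value=0.06, max_value=0.5),
       ratio=st.floats(min_value=0.6, max_value=0.869))   # ko/kd >= 1.15
def test_rounded_vs_unrounded_deuterium_factor(ko, ratio):
    """Replacing the printed factors (1.026/1.038/1.043) with exact
    1.007*DSR changes rCO2 by under 0.2% whenever ko/kd >= 1.15 (the
    infant factor 1.038 truncates 1.007*1.031 = 1.038217 and reaches
    0.18% right at the ko/kd = 1.15 boundary; the other two stay well
    under 0.15%)."""
    kd = ko * ratio
    for printed, dsr in [(1.026, 1.019), (1.038, 1.031), (1.043, 1.036)]:
        with_printed = 0.4554 * (1.007 * ko - printed * kd)
        with_exact = 0.4554 * (1.007 * ko - 1.007 * dsr * kd)
        assert abs(with_exact / with_printed - 1) < 2e-3
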