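"""The two-pool rCO2 equation family.

All variants share the structure

    rCO2 (L/d) = c * N * (1.007*ko - f*kd) * 22.26

where ``N`` is the body-water pool (mol), ``c = 1/2.078 - 0.0246*1.05``
(printed 0.4554) combines the pool-to-flux conversion with the
fractionation correction, 1.007 scales the 18O dilution space to body
water, and ``f = 1.007 * DSR`` folds in the population dilution-space
ratio. The variants differ only in the DSR they assume:

========== ===== ============ ==============================
variant     DSR   f (printed)  intended population
========== ===== ============ ==============================
adult      1.036  1.043        children, adolescents, adults
infant     1.031  1.038        babies 2-10 kg
preterm    1.019  1.026        preterm babies and neonates <2 kg
mass-dep.  DSR(BM)             babies <10 kg, continuous in mass
========== ===== ============ ==============================

The mass-dependent variant evaluates the DSR from body mass via the
asymptotic-exponential model (see :mod:`dlwcalc.dsr`) and uses the
collapsed form ``0.45859 * N * (ko - DSR*kd) * 22.26``, which removes
the boundary discontinuities of switching between fixed-DSR equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .constants import (
    ADULT_MASS_THRESHOLD_KG,
    COEFF_KO,
    COEFF_SIMPLIFIED,
    DEFAULT_CONSTANTS,
    DSR_ADULT,
    DSR_INFANT,
    DSR_PRETERM,
    KD_FACTOR_ADULT,
    KD_FACTOR_INFANT,
    KD_FACTOR_PRETERM,
    PhysicalConstants,
)
from .dsr import DEFAULT_DSR_PARAMS, DSRModelParams, dsr_from_mass
from .errors import ConfigurationError, DataError, NonPositiveProductionError
from .kinetics import IsotopeKinetics

logger = logging.getLogger("dlwcalc")

EquationId = Literal["adult", "preterm_1019", "infant_1031",
                     "mass_dependent", "generic"]
PoolConvention = Literal["two_pool_average", "oxygen_only"]


@dataclass(frozen=True)
class RCO2Result:
    """A computed CO2 production rate with full provenance."""

    rco2: float                      # L/d
    equation_id: EquationId
    pool_size_used: float            # mol
    dsr_used: float
    pool_convention: PoolConvention

    def rco2_mol_per_day(self,
                         constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        return self.rco2 / constants.co2_molar_volume


# ---------------------------------------------------------------------------
# pool-size conventions

def pool_size_two_pool(No: float, Nd: float) -> float:
    """Average body-water pool from both dilution spaces:
    N = (No/1.007 + Nd/1.043) / 2. Averaging halves the impact of
    analytical error in either space."""
    if not (No > 0 and Nd > 0):
        raise DataError(f"dilution spaces must be positive, got No={No!r}, Nd={Nd!r}")
    return (No / 1.007 + Nd / 1.043) / 2.0


def pool_size_oxygen(No: float) -> float:
    """Body-water pool from the 18O space alone: N = No/1.007."""
    if not No > 0:
        raise DataError(f"No must be positive, got {No!r}")
    return No / 1.007


def _resolve_pool(kin: IsotopeKinetics,
                  convention: PoolConvention) -> tuple[float, PoolConvention]:
    """Pool size per convention; falls back to the oxygen-only pool (with a
    logged note) when the two-pool average is requested but Nd is absent —
    an explicitly sanctioned simplification."""
    if convention == "two_pool_average":
        if kin.Nd is None:
            logger.info("subject %s: Nd absent, falling back to oxygen-only "
                        "pool N = No/1.007", kin.subject_id)
            return pool_size_oxygen(kin.No), "oxygen_only"
        return pool_size_two_pool(kin.No, kin.Nd), "two_pool_average"
    if convention == "oxygen_only":
        return pool_size_oxygen(kin.No), "oxygen_only"
    raise ConfigurationError(f"unknown pool convention {convention!r}")


# ---------------------------------------------------------------------------
# the equation family

def _check_flux(flux: float, *, N: float, ko: float, kd: float,
                dsr: float) -> None:
    if flux <= 0:
        raise NonPositiveProductionError(
            f"non-positive CO2 production: effective flux {flux:.6g} <= 0 for "
            f"ko={ko}, kd={kd}, DSR={dsr}, N={N} (isotope-analysis failure)",
            n=N, ko=ko, kd=kd, dsr=dsr)


def rco2_generic(N: float, ko: float, kd: float, dsr: float,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Generalized collapsed form rCO2 = 0.45859 * N * (ko - DSR*kd) * 22.26.

    Operates on an already-resolved pool size; the population-specific
    wrappers below add pool conventions and provenance.
    """
    if not N > 0:
        raise DataError(f"N must be positive, got {N!r}")
    if not (ko > 0 and kd > 0):
        raise DataError(f"rate constants must be positive, got ko={ko!r}, kd={kd!r}")
    if not (0.9 < dsr < 1.2):
        raise DataError(f"DSR {dsr!r} outside the supported range (0.9, 1.2)")
    flux = ko - dsr * kd
    _check_flux(flux, N=N, ko=ko, kd=kd, dsr=dsr)
    return COEFF_KO * N * flux * constants.co2_molar_volume


def _rco2_fixed_dsr(kin: IsotopeKinetics, *, kd_factor: float, dsr: float,
                    equation_id: EquationId, N: float,
                    pool_convention: PoolConvention,
                    constants: PhysicalConstants) -> RCO2Result:
    """Simplified printed form rCO2 = 0.4554 * N * (1.007*ko - f*kd) * 22.26
    with f the printed deuterium factor for the population DSR."""
    flux = 1.007 * kin.ko - kd_factor * kin.kd
    _check_flux(flux, N=N, ko=kin.ko, kd=kin.kd, dsr=dsr)
    rco2 = COEFF_SIMPLIFIED * N * flux * constants.co2_molar_volume
    return RCO2Result(rco2=rco2, equation_id=equation_id, pool_size_used=N,
                      dsr_used=dsr, pool_convention=pool_convention)


def rco2_adult(kin: IsotopeKinetics,
               pool_convention: PoolConvention = "two_pool_average",
               constants: PhysicalConstants = DEFAULT_CONSTANTS) -> RCO2Result:
    """Standard equation for subjects >=10 kg (DSR 1.036, factor 1.043).

    Uses the two-pool average pool by default, dropping to the oxygen-only
    pool when Nd is unavailable.
    """
    N, used = _resolve_pool(kin, pool_convention)
    return _rco2_fixed_dsr(kin, kd_factor=KD_FACTOR_ADULT, dsr=DSR_ADULT,
                           equation_id="adult", N=N, pool_convention=used,
                           constants=constants)


def rco2_preterm(kin: IsotopeKinetics,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> RCO2Result:
    """Preterm/neonate equation (<2 kg; DSR 1.019, factor 1.026),
    oxygen-only pool."""
    N = pool_size_oxygen(kin.No)
    return _rco2_fixed_dsr(kin, kd_factor=KD_FACTOR_PRETERM, dsr=DSR_PRETERM,
                           equation_id="preterm_1019", N=N,
                           pool_convention="oxygen_only", constants=constants)


def rco2_infant(kin: IsotopeKinetics,
                constants: PhysicalConstants = DEFAULT_CONSTANTS) -> RCO2Result:
    """Infant equation (2-10 kg; DSR 1.031, factor 1.038), oxygen-only pool."""
    N = pool_size_oxygen(kin.No)
    return _rco2_fixed_dsr(kin, kd_factor=KD_FACTOR_INFANT, dsr=DSR_INFANT,
                           equation_id="infant_1031", N=N,
                           pool_convention="oxygen_only", constants=constants)


def rco2_mass_dependent(kin: IsotopeKinetics,
                        dsr_params: DSRModelParams = DEFAULT_DSR_PARAMS,
                        literal_No_pool: bool = False,
                        constants: PhysicalConstants = DEFAULT_CONSTANTS,
                        ) -> RCO2Result:
    """Mass-dependent equation for babies <10 kg.

    The DSR is evaluated from body mass via the asymptotic-exponential
    model, then rCO2 = 0.45859 * N * (ko - DSR*kd) * 22.26. The pool is
    N = No/1.007 by default, consistent with the other baby equations;
    ``literal_No_pool=True`` uses N = No instead (the two readings differ
    by 0.7%).
    """
    if kin.body_mass is None:
        raise ConfigurationError(
            "mass-dependent equation requires body_mass on the kinetics record",
            subject_id=kin.subject_id)
    dsr = dsr_from_mass(kin.body_mass, dsr_params)
    N = kin.No if literal_No_pool else pool_size_oxygen(kin.No)
    rco2 = rco2_generic(N, kin.ko, kin.kd, dsr, constants=constants)
    return RCO2Result(rco2=rco2, equation_id="mass_dependent", pool_size_used=N,
                      dsr_used=dsr, pool_convention="oxygen_only")


def select_equation(body_mass: float | None) -> EquationId:
    """Automatic equation choice: adult at >=10 kg, mass-dependent below.

    The 10-kg boundary goes to the adult equation; the DSR curve is within
    0.03% of 1.036 there, so the switch is numerically seamless.
    """
    if body_mass is None:
        raise ConfigurationError(
            "body mass is required for automatic equation selection; choose "
            "an equation explicitly when mass is unknown")
    if not body_mass > 0:
        raise DataError(f"body mass must be positive, got {body_mass!r}")
    return "adult" if body_mass >= ADULT_MASS_THRESHOLD_KG else "mass_dependent"


def compute_rco2(kin: IsotopeKinetics,
                 equation: str = "auto",
                 pool_convention: PoolConvention = "two_pool_average",
                 generic_dsr: float | None = None,
                 dsr_params: DSRModelParams = DEFAULT_DSR_PARAMS,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> RCO2Result:
    """Dispatch a kinetics record to the requested (or auto-selected) equation."""
    if equation == "auto":
        equation = select_equation(kin.body_mass)
    if equation == "adult":
        return rco2_adult(kin, pool_convention, constants)
    if equation == "preterm_1019":
        return rco2_preterm(kin, constants)
    if equation == "infant_1031":
        return rco2_infant(kin, constants)
    if equation == "mass_dependent":
        return rco2_mass_dependent(kin, dsr_params, constants=constants)
    if equation == "generic":
        if generic_dsr is None:
            raise ConfigurationError("generic equation requires an explicit DSR")
        N, used = _resolve_pool(kin, pool_convention)
        rco2 = rco2_generic(N, kin.ko, kin.kd, generic_dsr, constants=constants)
        return RCO2Result(rco2=rco2, equation_id="generic", pool_size_used=N,
                          dsr_used=generic_dsr, pool_convention=used)
    raise ConfigurationError(f"unknown equation {equation!r}")
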