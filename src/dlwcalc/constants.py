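"""Physical constants of the two-pool DLW calculation.

The rCO2 equations share a small set of constants:

* ``pool_to_flux`` (2.078) converts the body-water pool into an isotope
  flux denominator,
* ``fractionation_correction`` x ``fractionated_water_fraction``
  (0.0246 * 1.05) removes the fractionated evaporative water loss,
* ``oxygen_space_factor`` (1.007) scales the 18O dilution space down to
  total body water (the 2H analogue is the population dilution-space
  ratio times 1.007, printed as 1.043 / 1.038 / 1.026 for DSR 1.036 /
  1.031 / 1.019),
* ``co2_molar_volume`` (22.26 L/mol) converts mol CO2/d to L/d. The
  ideal-gas 22.4 L/mol used historically overstates rCO2 by
  22.4/22.26 - 1 = 0.63% because CO2 is not an ideal gas; it is kept
  only for back-comparisons behind an explicit override.

Combining the first two gives the simplified coefficient
1/2.078 - 0.0246*1.05 = 0.45540, printed as 0.4554, and the fully
collapsed per-isotope coefficients 0.4554*1.007 = 0.45859 and
0.4554*1.043 = 0.47498.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

logger = logging.getLogger("dlwcalc")

#: Printed (rounded) coefficients used verbatim in the calculation forms.
COEFF_SIMPLIFIED = 0.4554        # 1/2.078 - 0.0246*1.05, rounded
COEFF_KO = 0.45859               # 0.4554 * 1.007
COEFF_KD_ADULT = 0.47498         # 0.4554 * 1.043

#: Printed deuterium factors (1.007 * DSR, rounded) per population.
KD_FACTOR_ADULT = 1.043          # DSR 1.036
KD_FACTOR_INFANT = 1.038         # DSR 1.031
KD_FACTOR_PRETERM = 1.026        # DSR 1.019

#: Population dilution-space ratios.
DSR_ADULT = 1.036
DSR_INFANT = 1.031
DSR_PRETERM = 1.019

#: Molar mass of water, g/mol, for dilution spaces supplied in kg.
WATER_MOLAR_MASS = 18.02

#: Body-mass boundary (kg) between the adult equation and the
#: mass-dependent DSR equation. The boundary itself goes to the adult
#: equation: the DSR curve evaluates to 1.03574 at 10 kg, within 0.03%
#: of the adult 1.036, so the discontinuity is negligible.
ADULT_MASS_THRESHOLD_KG = 10.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Read-only default constants; overrides go through :meth:`replace`
    so they are logged (an audit trail for the calculation provenance)."""

    pool_to_flux: float = 2.078
    fractionation_correction: float = 0.0246
    fractionated_water_fraction: float = 1.05
    oxygen_space_factor: float = 1.007
    co2_molar_volume: float = 22.26          # L/mol, real-gas CO2
    ideal_gas_molar_volume: float = 22.4     # L/mol, legacy comparisons only

    @property
    def flux_coefficient(self) -> float:
        """Unrounded simplified coefficient 1/2.078 - 0.0246*1.05."""
        return (1.0 / self.pool_to_flux
                - self.fractionation_correction * self.fractionated_water_fraction)

    def replace(self, **overrides) -> "PhysicalConstants":
        """Return a copy with ``overrides`` applied, logging each change."""
        for name, value in overrides.items():
            logger.warning("physical constant override: %s = %s (default %s)",
                           name, value, getattr(self, name))
        return dataclasses.replace(self, **overrides)


DEFAULT_CONSTANTS = PhysicalConstants()
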