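"""Per-subject isotope kinetic parameters.

An :class:`IsotopeKinetics` record is the unit of input to every rCO2
equation: the two elimination rate constants (ko for 18O, kd for 2H, both
in d^-1), the two dilution spaces (No required, Nd optional, mol), and
optionally the body mass (kg, needed for automatic equation selection)
and a respiratory or food quotient (needed for energy conversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .constants import WATER_MOLAR_MASS
from .errors import DataError, KineticsError

#: Physiological plausibility window for the individual dilution-space
#: ratio Nd/No. Values outside warn by default and hard-fail in strict mode.
DSR_PLAUSIBLE_LOW = 0.95
DSR_PLAUSIBLE_HIGH = 1.15


@dataclass(frozen=True)
class IsotopeKinetics:
    """One subject's isotope kinetics.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    ko, kd : float
        18O and 2H elimination rate constants, d^-1. ko must exceed kd:
        18O leaves as both water and CO2 so it always turns over faster.
    No : float
        18O dilution space, mol.
    Nd : float, optional
        2H dilution space, mol. When present, Nd/No must fall in the
        physiological window (0.95, 1.15).
    body_mass : float, optional
        Body mass, kg.
    rq : float, optional
        Respiratory quotient (or food quotient used in its place).
    strict_dsr : bool
        When True an implausible Nd/No raises instead of warning.
    """

    subject_id: str
    ko: float
    kd: float
    No: float
    Nd: float | None = None
    body_mass: float | None = None
    rq: float | None = None
    strict_dsr: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("ko", "kd", "No"):
            value = getattr(self, name)
            if not value > 0:
                raise DataError(f"{name} must be positive, got {value!r}",
                                field=name, value=value)
        for name in ("Nd", "body_mass", "rq"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DataError(f"{name} must be positive when given, got {value!r}",
                                field=name, value=value)
        if self.ko <= self.kd:
            raise KineticsError(
                f"ko ({self.ko}) must exceed kd ({self.kd}): 18O is eliminated "
                "as both water and CO2; ko <= kd indicates an isotope-analysis "
                "failure", ko=self.ko, kd=self.kd, subject_id=self.subject_id)
        if self.Nd is not None:
            ratio = self.Nd / self.No
            if not (DSR_PLAUSIBLE_LOW < ratio < DSR_PLAUSIBLE_HIGH):
                message = (f"dilution space ratio Nd/No = {ratio:.4f} outside the "
                           f"physiological window ({DSR_PLAUSIBLE_LOW}, "
                           f"{DSR_PLAUSIBLE_HIGH}) for subject {self.subject_id!r}")
                if self.strict_dsr:
                    raise KineticsError(message, dsr=ratio,
                                        subject_id=self.subject_id)
                warnings.warn(message, stacklevel=3)

    @property
    def dilution_space_ratio(self) -> float | None:
        """Individual Nd/No, or None when Nd was not measured."""
        return None if self.Nd is None else self.Nd / self.No


def mol_from_kg_water(kg: float) -> float:
    """Convert a dilution space given in kg of water to mol (18.02 g/mol)."""
    if not kg > 0:
        raise DataError(f"water mass must be positive, got {kg!r}")
    return kg * 1000.0 / WATER_MOLAR_MASS
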