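"""rCO2 -> total energy expenditure via the Weir equation.

TEE (MJ/d) = rCO2 * (1.106 + 3.94/RQ) * 4.184/1000, with rCO2 in L/d.

The respiratory quotient may be a measured RQ or a diet-derived food
quotient (FQ); the two enter the formula identically, so a single numeric
field with a provenance tag is used. No default RQ is assumed — energy is
only computed when one is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .errors import DataError

KCAL_PER_MJ = 1000.0 / 4.184

#: Physiological RQ range; values outside warn but still compute.
RQ_SOFT_LOW = 0.6
RQ_SOFT_HIGH = 1.3


@dataclass(frozen=True)
class EnergyResult:
    tee_mj_per_day: float
    tee_kcal_per_day: float
    rq_used: float
    rq_source: Literal["measured_rq", "food_quotient"]


def weir_tee(rco2: float, rq: float,
             rq_source: Literal["measured_rq", "food_quotient"] = "measured_rq",
             ) -> EnergyResult:
    """Convert a CO2 production rate (L/d) to TEE given an RQ or FQ."""
    if not rco2 > 0:
        raise DataError(f"rco2 must be positive, got {rco2!r}")
    if not rq > 0:
        raise DataError(f"RQ must be positive, got {rq!r}")
    if not (RQ_SOFT_LOW <= rq <= RQ_SOFT_HIGH):
        warnings.warn(f"RQ {rq} outside the physiological range "
                      f"[{RQ_SOFT_LOW}, {RQ_SOFT_HIGH}]", stacklevel=2)
    tee_mj = rco2 * (1.106 + 3.94 / rq) * 4.184 / 1000.0
    return EnergyResult(tee_mj_per_day=tee_mj,
                        tee_kcal_per_day=tee_mj * KCAL_PER_MJ,
                        rq_used=rq, rq_source=rq_source)
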