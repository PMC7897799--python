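"""Packaged validation tables and the synthetic isotope-kinetics generator.

Two fixture tables ship with the package as checksum-verified CSV
transcriptions of published chamber-calorimetry validation studies:

* ``table1_adults.csv`` — 61 adults; chamber rCO2 plus rCO2 and percent
  deviation recomputed under six calculation methods (the standard adult
  equation labelled ``eq1`` plus five legacy equations transcribed as
  data). Two legacy columns require Nd and exist for only 35 subjects.
* ``table2_babies.csv`` — 34 preterm and neonatal babies (24 under 2 kg,
  10 over); chamber rCO2 plus the adult, preterm (``eq6``), infant
  (``eq7``), mass-dependent (``eq10``) and two legacy columns. Body mass
  is stored in grams as printed and converted to kg on load.

The module also provides:

* a synthetic cohort generator that emulates two-pool isotope kinetics
  (pool from body water, ko solved so each noise-free subject reproduces
  a target rCO2 exactly, Nd set from the mass-appropriate DSR) with
  multiplicative measurement noise, and
* a kinetics "back-out" oracle: because the preterm and infant equations
  are linear in (N*ko, N*kd) and differ only in the deuterium factor,
  their two printed columns can be solved for the products N*kd and
  N*ko, letting the mass-dependent column be reconstructed without the
  unpublished raw kinetics.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .constants import (
    ADULT_MASS_THRESHOLD_KG,
    COEFF_KO,
    COEFF_SIMPLIFIED,
    DEFAULT_CONSTANTS,
    DSR_ADULT,
    KD_FACTOR_ADULT,
    KD_FACTOR_INFANT,
    KD_FACTOR_PRETERM,
    WATER_MOLAR_MASS,
)
from .dsr import DEFAULT_DSR_PARAMS, DSRModelParams, dsr_from_mass
from .equations import pool_size_two_pool
from .errors import DataError, FixtureError
from .kinetics import IsotopeKinetics

_CHECKSUMS = {
    "table1_adults.csv":
        "d351311131ace4c7fdf9cd0e03304fbc6f2f8e0785df394bb90476edfa259d9f",
    "table2_babies.csv":
        "40eaa189e226472f368bed8b33d8bb670eb233c429f0ff69d2ce989d1bcd6f08",
}

TABLE1_EQUATION_COLUMNS = ("schoeller1988", "racette1994", "eq1",
                           "speakman1997", "speakman1993", "coward1985")
TABLE2_EQUATION_COLUMNS = ("eq1", "eq6", "eq7", "coward1985",
                           "speakman717", "eq10")


@dataclass(frozen=True)
class ValidationRecord:
    """One row of a validation table: chamber rCO2 plus per-equation
    rCO2 / percent-deviation pairs (None where not computable)."""

    source_study: str
    subject_id: str
    body_mass: float                     # kg
    rco2_ic: float                       # L/d
    rco2_by_equation: dict[str, float | None]
    pct_by_equation: dict[str, float | None]


def _load_fixture(name: str, expected_rows: int) -> pd.DataFrame:
    path = resources.files("dlwcalc.data").joinpath(name)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"fixture {name} failed its checksum: sha256 {digest} "
                           f"!= expected {_CHECKSUMS[name]}", fixture=name)
    import io
    df = pd.read_csv(io.BytesIO(raw))
    if len(df) != expected_rows:
        raise FixtureError(f"fixture {name} has {len(df)} rows, "
                           f"expected {expected_rows}", fixture=name)
    return df


def load_table1() -> pd.DataFrame:
    """The 61-adult validation table (columns in L/d and %, mass in kg)."""
    return _load_fixture("table1_adults.csv", 61)


def load_table2() -> pd.DataFrame:
    """The 34-baby validation table; adds ``body_mass_kg`` converted from
    the printed grams."""
    df = _load_fixture("table2_babies.csv", 34)
    df["body_mass_kg"] = df["body_mass_g"] / 1000.0
    return df


def iter_validation_records(df: pd.DataFrame, table: int):
    """Yield :class:`ValidationRecord` objects from a loaded table."""
    columns = TABLE1_EQUATION_COLUMNS if table == 1 else TABLE2_EQUATION_COLUMNS
    source_col = "source" if table == 1 else "study"
    for _, row in df.iterrows():
        def _get(name):
            value = row[name]
            return None if pd.isna(value) else float(value)
        yield ValidationRecord(
            source_study=row[source_col], subject_id=str(row["subject_id"]),
            body_mass=float(row["body_mass_kg"]),
            rco2_ic=float(row["rco2_ic_L_per_day"]),
            rco2_by_equation={c: _get(f"{c}_L_per_day") for c in columns},
            pct_by_equation={c: _get(f"{c}_pct") for c in columns})


# ---------------------------------------------------------------------------
# kinetics back-out oracle

class KineticsProducts(NamedTuple):
    """Products of the body-water pool N = No/1.007 with the rate
    constants, recovered from the preterm/infant equation pair."""

    pool_kd: float    # N * kd, mol/d
    pool_ko: float    # N * ko, mol/d


def backout_kinetics_products(rco2_preterm_eq: float, rco2_infant_eq: float,
                              ) -> KineticsProducts:
    """Solve the preterm (factor 1.026) and infant (factor 1.038) equation
    pair for N*kd and N*ko.

    Both equations read 0.4554 * N * (1.007*ko - f*kd) * 22.26, so their
    difference isolates N*kd:

        N*kd = (rco2_preterm - rco2_infant) / (0.4554 * 0.012 * 22.26)
    """
    if rco2_preterm_eq is None or rco2_infant_eq is None or \
            math.isnan(rco2_preterm_eq) or math.isnan(rco2_infant_eq):
        raise DataError("both equation columns are required for the back-out")
    c = COEFF_SIMPLIFIED * DEFAULT_CONSTANTS.co2_molar_volume
    factor_gap = KD_FACTOR_INFANT - KD_FACTOR_PRETERM   # 0.012
    pool_kd = (rco2_preterm_eq - rco2_infant_eq) / (c * factor_gap)
    pool_ko = (rco2_preterm_eq / c + KD_FACTOR_PRETERM * pool_kd) / 1.007
    if pool_kd <= 0 or pool_ko <= pool_kd:
        raise DataError("back-out produced non-physical products",
                        pool_kd=pool_kd, pool_ko=pool_ko)
    return KineticsProducts(pool_kd=pool_kd, pool_ko=pool_ko)


def reconstruct_eq10_column(table2: pd.DataFrame,
                            dsr_params: DSRModelParams = DEFAULT_DSR_PARAMS,
                            ) -> pd.Series:
    """Reconstruct the mass-dependent rCO2 column from the preterm and
    infant columns via the back-out oracle, evaluating the DSR at each
    printed body mass."""
    out = []
    for _, row in table2.iterrows():
        products = backout_kinetics_products(row["eq6_L_per_day"],
                                             row["eq7_L_per_day"])
        dsr = dsr_from_mass(row["body_mass_g"] / 1000.0, dsr_params)
        out.append(COEFF_KO * (products.pool_ko - dsr * products.pool_kd)
                   * DEFAULT_CONSTANTS.co2_molar_volume)
    return pd.Series(out, index=table2.index, name="eq10_reconstructed")


# ---------------------------------------------------------------------------
# synthetic cohort generator

def default_target_rco2(mass_kg: float) -> float:
    """Allometric default for the expected rCO2 (L/d) at a given mass,
    12.5 * BM^0.84, anchored to the validation-cohort means (~18.9 L/d at
    1.63 kg for babies, ~497 L/d at 80.5 kg for adults)."""
    return 12.5 * mass_kg ** 0.84


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for a synthetic cohort.

    Defaults describe a free-living adult cohort: masses uniform on
    50-100 kg, body water 50-65% of mass, 2H elimination 0.07-0.10 d^-1,
    1% multiplicative measurement noise on each kinetic parameter.
    """

    n: int = 100
    mass_range: tuple[float, float] = (50.0, 100.0)          # kg
    water_fraction_range: tuple[float, float] = (0.50, 0.65)
    kd_range: tuple[float, float] = (0.07, 0.10)             # d^-1
    target_rco2_model: Callable[[float], float] = field(
        default=default_target_rco2)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError(f"n must be >= 1, got {self.n}")
        for name in ("mass_range", "water_fraction_range", "kd_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise DataError(f"invalid {name}: ({lo}, {hi})")
        if self.noise_sd < 0:
            raise DataError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SyntheticCohort:
    spec: SyntheticCohortSpec
    kinetics: tuple[IsotopeKinetics, ...]
    true_rco2: np.ndarray      # noise-free target rCO2 per subject, L/d

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical input-CSV schema plus the noise-free truth column."""
        return pd.DataFrame({
            "subject_id": [k.subject_id for k in self.kinetics],
            "ko_perday": [k.ko for k in self.kinetics],
            "kd_perday": [k.kd for k in self.kinetics],
            "No_mol": [k.No for k in self.kinetics],
            "Nd_mol": [k.Nd for k in self.kinetics],
            "body_mass_kg": [k.body_mass for k in self.kinetics],
            "true_rco2_L_per_day": self.true_rco2,
        })


_MAX_NOISE_ATTEMPTS = 1000


def _solve_ko(mass: float, N: float, No: float, Nd: float, kd: float,
              target: float, dsr_params: DSRModelParams) -> float:
    """Invert the equation that automatic selection will apply to this
    subject, so the noise-free record reproduces ``target`` exactly."""
    mv = DEFAULT_CONSTANTS.co2_molar_volume
    if mass >= ADULT_MASS_THRESHOLD_KG:
        n_eq = pool_size_two_pool(No, Nd)
        return (target / (COEFF_SIMPLIFIED * n_eq * mv)
                + KD_FACTOR_ADULT * kd) / 1.007
    dsr = dsr_from_mass(mass, dsr_params)
    return target / (COEFF_KO * N * mv) + dsr * kd


def generate_synthetic_cohort(spec: SyntheticCohortSpec,
                              dsr_params: DSRModelParams = DEFAULT_DSR_PARAMS,
                              ) -> SyntheticCohort:
    """Draw a cohort of isotope-kinetics records consistent with the
    two-pool model.

    For each subject: body water (mass x water fraction, converted to mol
    at 18.02 g/mol) gives the pool; No = 1.007*N; Nd = DSR*No with DSR
    1.036 at >=10 kg or the mass-dependent curve below; kd is drawn
    uniformly; ko is solved so the noise-free record reproduces the
    target rCO2 exactly under the equation automatic selection would
    apply. Multiplicative Gaussian noise (SD ``noise_sd``) then perturbs
    ko, kd, No and Nd independently; a subject's noise draw is rejected
    and redrawn if it violates the kinetics invariants (ko > kd,
    plausible Nd/No), so every emitted record is physically valid.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.target_rco2_model
    kinetics: list[IsotopeKinetics] = []
    targets = np.empty(spec.n)
    for i in range(spec.n):
        mass = rng.uniform(*spec.mass_range)
        water_fraction = rng.uniform(*spec.water_fraction_range)
        kd = rng.uniform(*spec.kd_range)
        N = mass * water_fraction * 1000.0 / WATER_MOLAR_MASS
        No = N * 1.007
        dsr_true = (DSR_ADULT if mass >= ADULT_MASS_THRESHOLD_KG
                    else dsr_from_mass(mass, dsr_params))
        Nd = dsr_true * No
        target = float(model(mass))
        if not target > 0:
            raise DataError(f"target rCO2 model returned {target!r} "
                            f"at mass {mass:.3g} kg")
        ko = _solve_ko(mass, N, No, Nd, kd, target, dsr_params)
        if ko <= kd:
            raise DataError(
                f"target rCO2 {target:.3g} L/d at mass {mass:.3g} kg is "
                f"incompatible with kd={kd:.3g} d^-1 (inversion gives "
                f"ko={ko:.3g} <= kd)", mass=mass, kd=kd, target=target)
        for attempt in range(_MAX_NOISE_ATTEMPTS):
            factors = 1.0 + spec.noise_sd * rng.standard_normal(4)
            ko_n, kd_n, No_n, Nd_n = (ko * factors[0], kd * factors[1],
                                      No * factors[2], Nd * factors[3])
            if min(ko_n, kd_n, No_n, Nd_n) <= 0 or ko_n <= kd_n:
                continue
            if not (0.95 < Nd_n / No_n < 1.15):
                continue
            break
        else:
            raise DataError(f"could not draw valid noise for subject {i} "
                            f"after {_MAX_NOISE_ATTEMPTS} attempts")
        kinetics.append(IsotopeKinetics(
            subject_id=f"S{i:04d}", ko=ko_n, kd=kd_n, No=No_n, Nd=Nd_n,
            body_mass=mass))
        targets[i] = target
    return SyntheticCohort(spec=spec, kinetics=tuple(kinetics),
                           true_rco2=targets)
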