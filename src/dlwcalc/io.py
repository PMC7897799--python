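"""Tabular input/output and the row-wise computation pipeline.

Canonical input CSV schema (UTF-8, period decimal separator, header
required)::

    subject_id, ko_perday, kd_perday, No_mol [, Nd_mol, body_mass_kg, rq]

Output rows carry the input columns plus ``rco2_L_per_day``,
``equation_id``, ``dsr_used``, ``pool_size_mol``, ``pool_convention``
and, when an RQ/FQ is present, ``tee_MJ_per_day``. In strict mode any
row-level failure aborts the run; otherwise failed rows get an ``error``
column entry (the machine-readable error code plus message) and the rest
proceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .dsr import DEFAULT_DSR_PARAMS, DSRModelParams
from .energy import weir_tee
from .equations import PoolConvention, compute_rco2
from .errors import ConfigurationError, DataError, DLWError
from .kinetics import IsotopeKinetics, mol_from_kg_water

logger = logging.getLogger("dlwcalc")

REQUIRED_COLUMNS = ("subject_id", "ko_perday", "kd_perday", "No_mol")
OPTIONAL_COLUMNS = ("Nd_mol", "body_mass_kg", "rq")


@dataclass(frozen=True)
class RunConfig:
    """Effective settings for a computation run.

    ``equation_choice`` is one of auto / adult / preterm_1019 /
    infant_1031 / mass_dependent / generic (generic additionally needs
    ``generic_dsr``). ``dilution_space_unit`` may be ``mol`` (canonical)
    or ``kg`` of water (converted at 18.02 g/mol). ``molar_volume``
    defaults to the real-gas 22.26 L/mol; overriding it (e.g. to the
    legacy 22.4) is logged.
    """

    equation_choice: str = "auto"
    generic_dsr: float | None = None
    pool_convention: PoolConvention = "two_pool_average"
    molar_volume: float = DEFAULT_CONSTANTS.co2_molar_volume
    dsr_params: DSRModelParams = field(default=DEFAULT_DSR_PARAMS)
    dilution_space_unit: str = "mol"
    report_mol_per_day: bool = False
    strict_validation: bool = False

    def constants(self) -> PhysicalConstants:
        if self.molar_volume != DEFAULT_CONSTANTS.co2_molar_volume:
            return DEFAULT_CONSTANTS.replace(co2_molar_volume=self.molar_volume)
        return DEFAULT_CONSTANTS

    def log_effective(self) -> None:
        """Audit trail: record every constant and setting in effect."""
        logger.info("run config: equation=%s pool=%s molar_volume=%s "
                    "dsr_params=(%.4f, %.4f, %.4f) unit=%s strict=%s",
                    self.equation_choice, self.pool_convention,
                    self.molar_volume, self.dsr_params.asymptote,
                    self.dsr_params.amplitude, self.dsr_params.rate,
                    self.dilution_space_unit, self.strict_validation)


def read_kinetics_csv(path) -> pd.DataFrame:
    """Read and validate a canonical kinetics CSV.

    Rejects empty files, missing required columns and comma decimal
    separators (the schema is locale-independent: period decimals only).
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ConfigurationError(f"input file {path} is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"input file {path} lacks required columns: "
                        f"{', '.join(missing)}", missing=missing)
    if len(df) == 0:
        raise ConfigurationError(f"input file {path} has a header but no rows")
    numeric = [c for c in REQUIRED_COLUMNS[1:] + OPTIONAL_COLUMNS
               if c in df.columns]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            offending = df[col].astype(str)
            if offending.str.contains(",").any():
                raise DataError(
                    f"column {col!r} contains comma decimal separators; "
                    "the schema requires period decimals") from exc
            raise DataError(f"column {col!r} is not numeric: {exc}") from exc
    return df


def _row_kinetics(row: pd.Series, config: RunConfig) -> IsotopeKinetics:
    def _opt(name):
        value = row.get(name)
        return None if value is None or pd.isna(value) else float(value)

    No = float(row["No_mol"])
    Nd = _opt("Nd_mol")
    if config.dilution_space_unit == "kg":
        No = mol_from_kg_water(No)
        Nd = None if Nd is None else mol_from_kg_water(Nd)
    return IsotopeKinetics(
        subject_id=str(row["subject_id"]), ko=float(row["ko_perday"]),
        kd=float(row["kd_perday"]), No=No, Nd=Nd,
        body_mass=_opt("body_mass_kg"), rq=_opt("rq"),
        strict_dsr=config.strict_validation)


def compute_dataframe(df: pd.DataFrame,
                      config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Apply the configured rCO2 (and, where RQ is present, TEE)
    computation to every row of a canonical kinetics table."""
    config.log_effective()
    constants = config.constants()
    out = df.copy()
    n = len(df)
    rco2 = np.full(n, np.nan)
    tee = np.full(n, np.nan)
    pool = np.full(n, np.nan)
    dsr = np.full(n, np.nan)
    eq_id = np.full(n, None, dtype=object)
    pool_conv = np.full(n, None, dtype=object)
    errors = np.full(n, None, dtype=object)
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            kin = _row_kinetics(row, config)
            result = compute_rco2(kin, equation=config.equation_choice,
                                  pool_convention=config.pool_convention,
                                  generic_dsr=config.generic_dsr,
                                  dsr_params=config.dsr_params,
                                  constants=constants)
            rco2[i] = result.rco2
            pool[i] = result.pool_size_used
            dsr[i] = result.dsr_used
            eq_id[i] = result.equation_id
            pool_conv[i] = result.pool_convention
            if kin.rq is not None:
                tee[i] = weir_tee(result.rco2, kin.rq).tee_mj_per_day
        except DLWError as exc:
            if config.strict_validation:
                raise
            errors[i] = f"{exc.code}: {exc}"
            logger.warning("row %d (%s) failed: %s", i,
                           row.get("subject_id"), exc)
    out["rco2_L_per_day"] = rco2
    out["equation_id"] = eq_id
    out["dsr_used"] = dsr
    out["pool_size_mol"] = pool
    out["pool_convention"] = pool_conv
    out["tee_MJ_per_day"] = tee
    if config.report_mol_per_day:
        out["rco2_mol_per_day"] = rco2 / constants.co2_molar_volume
    if any(e is not None for e in errors):
        out["error"] = errors
    return out
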