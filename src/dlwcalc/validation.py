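"""Validation summaries of the packaged chamber-calorimetry tables.

Reproduces the table-footer statistics: for each equation column the n,
mean and SD of the percent deviations from indirect calorimetry and the
one-sample t-test of the mean against zero, plus (for the baby table)
the regression of the mass-dependent predictions on the chamber values.
"""

from __future__ import annotations

import pandas as pd

from .datasets import (
    TABLE1_EQUATION_COLUMNS,
    TABLE2_EQUATION_COLUMNS,
    load_table1,
    load_table2,
)
from .errors import ConfigurationError
from .stats import RegressionResult, ols_with_rma, summarize_deviations


def deviation_table(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Summarize the percent-deviation column of each equation: one row
    per equation with n, mean, SD, t and p."""
    rows = []
    for col in columns:
        s = summarize_deviations(df[f"{col}_pct"])
        rows.append({"equation": col, "n": s.n, "mean_pct": s.mean,
                     "sd_pct": s.sd, "t": s.t_statistic, "p": s.p_value})
    return pd.DataFrame(rows)


def table2_regression(df: pd.DataFrame | None = None) -> RegressionResult:
    """Regress the mass-dependent rCO2 predictions on the chamber values
    across all 34 babies (OLS slope/intercept, r^2, RMA slope)."""
    if df is None:
        df = load_table2()
    return ols_with_rma(df["rco2_ic_L_per_day"], df["eq10_L_per_day"])


def validation_report(table: int) -> dict:
    """Full validation summary for table 1 (adults) or 2 (babies).

    Table 2 reports the under-2-kg and over-2-kg subgroups separately
    (matching the published layout) plus the whole-sample summary of the
    mass-dependent column and the prediction-on-chamber regression.
    """
    if table == 1:
        df = load_table1()
        return {"table": 1, "n": len(df),
                "summary": deviation_table(df, TABLE1_EQUATION_COLUMNS)}
    if table == 2:
        df = load_table2()
        under = df[df["body_mass_kg"] < 2.0]
        over = df[df["body_mass_kg"] >= 2.0]
        return {
            "table": 2, "n": len(df),
            "summary_under_2kg": deviation_table(under, TABLE2_EQUATION_COLUMNS[:-1]),
            "summary_over_2kg": deviation_table(
                over, [c for c in TABLE2_EQUATION_COLUMNS[:-1] if c != "coward1985"]),
            "summary_eq10_all": deviation_table(df, ["eq10"]),
            "summary_eq10_over_2kg": deviation_table(over, ["eq10"]),
            "regression": table2_regression(df),
        }
    raise ConfigurationError(f"unknown validation table {table!r}; "
                             "available tables are 1 and 2")
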