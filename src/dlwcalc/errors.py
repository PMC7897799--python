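"""Structured exceptions with machine-readable codes.

Every error raised by the computational core derives from :class:`DLWError`
and carries a short ``code`` string so that batch pipelines (and the CLI's
row-level error column) can classify failures without parsing messages.
"""

from __future__ import annotations


class DLWError(Exception):
    """Base class for all package errors."""

    code: str = "dlw_error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class DataError(DLWError):
    """Invalid input data (bad kinetics, malformed files)."""

    code = "data_error"


class KineticsError(DataError):
    """Isotope kinetics violate a physical invariant.

    The canonical case is ko <= kd: 18O leaves the body as both water and
    CO2 while 2H leaves only as water, so the 18O elimination rate must be
    the faster of the two. A violation implies a failed isotope analysis,
    not a computable edge case.
    """

    code = "ko_le_kd"


class NonPositiveProductionError(DataError):
    """The isotope flux difference implies zero or negative CO2 production.

    Carries the offending values in ``context`` (``n``, ``ko``, ``kd``,
    ``dsr``) so the failure can be traced back to the sample.
    """

    code = "non_positive_rco2"


class ConfigurationError(DLWError):
    """A required setting is missing or inconsistent (e.g. automatic
    equation selection without a body mass)."""

    code = "configuration_error"


class FitConvergenceError(DLWError):
    """The nonlinear DSR fit failed to converge; ``context`` holds the
    optimizer trace (function-evaluation count, final residuals)."""

    code = "fit_no_convergence"


class FixtureError(DLWError):
    """A packaged validation table failed its checksum or shape check."""

    code = "fixture_corrupt"
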