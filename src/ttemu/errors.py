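"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3,
EstimationError -> 4.
"""


class TTEmuError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TTEmuError):
    """Invalid configuration value; message names the offending field."""


class DataError(TTEmuError):
    """Input data violates a documented schema invariant."""


class PatientLookupError(DataError):
    """A patient identifier is absent from the claims tables."""


class EstimationError(TTEmuError):
    """A model failed to fit (separation, non-convergence, zero events).

    Carries an optional ``diagnostics`` dict with whatever the failing
    stage could salvage (event counts, convergence trace, coefficients).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
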