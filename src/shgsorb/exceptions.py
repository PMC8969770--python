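"""Exception hierarchy for shgsorb."""


class ShgSorbError(Exception):
    """Base class for all shgsorb errors."""


class InvalidInputError(ShgSorbError, ValueError):
    """An input value violates a documented precondition."""


class InternalConsistencyError(ShgSorbError, RuntimeError):
    """A guarded impossible state was reached (e.g. negative discriminant)."""


class BracketError(ShgSorbError, ValueError):
    """A root bracket does not contain a sign change."""


class RangeError(ShgSorbError, ValueError):
    """A requested window or index lies outside the data grid."""


class FlatSpectrumError(ShgSorbError, ValueError):
    """A peak fit was requested on a degenerate, featureless spectrum."""


class InsufficientDataError(ShgSorbError, ValueError):
    """Not enough points/records to perform the requested operation."""


class FitError(ShgSorbError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(ShgSorbError, ValueError):
    """A run configuration is invalid or incomplete."""


class StageError(ShgSorbError, RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str, input_name: str | None = None):
        self.stage = stage
        self.input_name = input_name
        detail = f" (input: {input_name})" if input_name else ""
        super().__init__(f"stage '{stage}' failed{detail}: {message}")
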