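"""Exception hierarchy for thermocap."""


class ThermocapError(Exception):
    """Base class for all thermocap-specific errors."""


class EnergyTableParseError(ThermocapError, ValueError):
    """A data row of an energy table could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class SchemaError(ThermocapError, ValueError):
    """Required metadata (system label, temperature, ...) is missing."""


class LabelMismatchError(ThermocapError, ValueError):
    """Traces with different system labels were mixed in one aggregation."""


class InsufficientDataError(ThermocapError, ValueError):
    """Too few frames/points for the requested operation."""


class SelectionError(ThermocapError, ValueError):
    """An atom selector matched zero or more than one atom."""


class AlignmentError(ThermocapError, ValueError):
    """Mismatched array lengths / atom counts between paired inputs."""


class FitError(ThermocapError, RuntimeError):
    """A nonlinear fit failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class PipelineError(ThermocapError, RuntimeError):
    """Configuration or stage failure in an end-to-end pipeline run."""


class UnalignedEnsembleWarning(UserWarning):
    """An RMSF was requested on an ensemble whose frames appear unsuperposed."""
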