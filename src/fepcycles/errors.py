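"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors exit 2 (click's own),
data/parse/composition errors exit 3, estimator non-convergence exits 4.
"""


class FepcyclesError(Exception):
    """Base class for all fepcycles errors."""


class FepInputError(FepcyclesError, ValueError):
    """Invalid input data (non-finite samples, empty lists, bad values)."""


class ConvergenceError(FepcyclesError, RuntimeError):
    """The BAR self-consistency root could not be bracketed or refined.

    Carries overlap diagnostics so the caller can see how far apart the
    two ensembles are.
    """

    def __init__(self, message: str, mean_i: float | None = None,
                 mean_j: float | None = None):
        super().__init__(message)
        self.mean_i = mean_i
        self.mean_j = mean_j


class CompositionError(FepcyclesError, ValueError):
    """Leg annotations do not match the thermodynamic-cycle template."""


class ParseError(FepcyclesError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ExternalDataError(FepcyclesError, FileNotFoundError):
    """External data (e.g. the deposited raw FEP output) is required."""
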