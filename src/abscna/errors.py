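"""Exception hierarchy.

All package errors derive from :class:`AbscnaError` so callers can catch one
type; the pipeline wraps stage failures in :class:`StageError` carrying the
stage name.
"""


class AbscnaError(Exception):
    """Base class for all package errors."""


class FormatError(AbscnaError, ValueError):
    """A file is missing required columns or has the wrong layout."""


class ParseError(AbscnaError, ValueError):
    """A value in a file could not be parsed (carries the line number)."""


class ValidationError(AbscnaError, ValueError):
    """Input data violates an invariant (e.g. duplicate loci)."""


class ParameterError(AbscnaError, ValueError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(AbscnaError, ValueError):
    """Too few loci/values for the requested estimate."""


class NoDeletionsError(AbscnaError, RuntimeError):
    """No deletion segments were found; tumor purity is not estimable."""


class NotADeletionError(AbscnaError, ValueError):
    """A segment offered for deletion typing is not a deletion candidate."""


class StageError(AbscnaError, RuntimeError):
    """A pipeline stage failed; ``stage`` names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
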