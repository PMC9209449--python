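"""Exception hierarchy.

All package-specific failures derive from :class:`EpicarpError` so callers can
catch one base class; the subclasses distinguish configuration mistakes from
malformed data and from analysis-stage failures (the CLI maps them to distinct
exit codes).
"""


class EpicarpError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(EpicarpError, ValueError):
    """An invalid parameter or configuration value; names the offending field."""


class FormatError(EpicarpError, ValueError):
    """A malformed on-disk artifact; names the first offending record."""


class ValidationError(EpicarpError, ValueError):
    """An in-memory table violating a structural invariant."""


class StandardNotFoundError(EpicarpError, LookupError):
    """The internal-standard phylotype could not be resolved in the data."""


class AmbiguousStandardError(EpicarpError, LookupError):
    """More than one phylotype matches the internal standard."""


class StageError(EpicarpError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
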