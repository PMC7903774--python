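"""Exception hierarchy for the concordance pipeline.

Every stage raises a subclass of :class:`SynconcordError` so the CLI can
abort with a stage-named message and a nonzero exit status.
"""


class SynconcordError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SynconcordError):
    """An invalid configuration value; the message names the offending field."""


class InputError(SynconcordError):
    """Malformed or inconsistent input data."""


class DataError(SynconcordError):
    """A data-content problem detected mid-pipeline (e.g. forbidden duplicates)."""


class ParameterError(SynconcordError):
    """An invalid operation parameter (e.g. odd subset size)."""


class UndefinedCorrelationError(SynconcordError):
    """Correlation is undefined: fewer than 3 complete pairs or zero variance.

    Raised rather than returning NaN silently; sweep drivers catch it and
    record the reason alongside an empty cell.
    """


class ValidationError(SynconcordError):
    """Input validation failed; carries a list of issues."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))
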