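"""Exception hierarchy for treesilience."""


class TreesilienceError(Exception):
    """Base class for all package errors."""


class ConfigError(TreesilienceError):
    """Invalid configuration (synthetic generator or pipeline run)."""


class RwlFormatError(TreesilienceError):
    """Malformed Tucson decadal (.rwl) file."""

    def __init__(self, message, path=None, lineno=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if lineno is not None:
            loc += f":{lineno}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.lineno = lineno


class DatasetValidationError(TreesilienceError):
    """Dataset assembly failed validation; carries the list of offenders."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


class SeriesTooShortError(TreesilienceError):
    """A ring-width series is too short for the requested operation."""
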