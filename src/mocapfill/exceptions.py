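"""Exception hierarchy for mocapfill."""


class MocapFillError(Exception):
    """Base class for all mocapfill errors."""


class FormatError(MocapFillError):
    """A file does not conform to the expected container format."""


class ParameterError(MocapFillError, ValueError):
    """An algorithm or generator parameter is outside its valid domain."""


class InsufficientSupportError(MocapFillError):
    """Too few complete frames (or usable markers) to fit the PC bases."""

    def __init__(self, message: str, n_complete: int | None = None):
        super().__init__(message)
        self.n_complete = n_complete


class DegenerateBasisError(MocapFillError):
    """The training matrix has no variance to decompose."""


class NoCommonSupportError(MocapFillError):
    """Two markers share no frame in which both are observed."""
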