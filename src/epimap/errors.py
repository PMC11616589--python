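"""Exception hierarchy shared across the package."""


class EpimapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EpimapError):
    """A file could not be parsed (missing sidecar, malformed table, ...)."""


class ValidationError(EpimapError):
    """An in-memory object violates one of its structural invariants."""


class ManifestError(EpimapError):
    """Cohort manifest is inconsistent (dangling path, duplicate position)."""


class ParameterError(EpimapError):
    """A parameter is outside its admissible range."""


class AnnotationError(EpimapError):
    """Electrogram annotation could not be performed on the given window."""


class PairingError(EpimapError):
    """Two sample series could not be paired (mismatched time points)."""


class DataError(EpimapError):
    """Inconsistent data passed to an analysis step (e.g. duplicate entries)."""
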