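"""Exception hierarchy.

All data/validation failures raise a subclass of :class:`CosmixError` so the
command-line layer can map them onto a single exit code (3), distinct from
usage errors (2).
"""


class CosmixError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CosmixError):
    """An input table is missing required columns or has malformed values."""


class PanelError(CosmixError):
    """Reference panel is unreadable, empty, or internally inconsistent."""


class HarmonizationError(CosmixError):
    """Study rows cannot be reconciled with the panel (e.g. duplicates)."""


class InsufficientDataError(CosmixError):
    """Too few usable variants remain after filtering."""


class NumericalError(CosmixError):
    """A linear-algebra step failed (singular system, non-PSD matrix)."""


class DegenerateGeneError(CosmixError):
    """All weight categories of a gene carry zero variance under the LD."""


class ConfigError(CosmixError):
    """Invalid simulation or run configuration."""
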