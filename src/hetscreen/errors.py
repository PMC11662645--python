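"""Exception types shared across the pipeline."""


class HetscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HetscreenError):
    """A table is structurally malformed (missing columns, bad header)."""


class IntegrityError(HetscreenError):
    """A table violates a uniqueness or referential constraint."""


class AmbiguityError(HetscreenError):
    """A correction record is self-contradictory."""


class DegenerateDataError(HetscreenError):
    """A dataset is degenerate for the requested statistic (e.g. zero SD)."""


class ConfigError(HetscreenError):
    """Invalid configuration."""
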