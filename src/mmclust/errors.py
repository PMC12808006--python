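"""Exception hierarchy shared across the package."""


class MMClustError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MMClustError, ValueError):
    """Input table does not match the expected column schema."""


class CohortValidationError(MMClustError, ValueError):
    """Cohort values violate an invariant (binarity, non-negativity, multimorbidity)."""


class GenerationError(MMClustError, RuntimeError):
    """Synthetic cohort generation failed (e.g. rejection budget exhausted)."""


class ZeroVarianceError(MMClustError, ValueError):
    """A clustering column has zero variance and cannot be standardized."""


class InitializationError(MMClustError, ValueError):
    """K-means initialization is infeasible (duplicate or insufficient centroids)."""


class AlignmentError(MMClustError, ValueError):
    """Assignment vector is not aligned with the cohort rows."""


class ConfigError(MMClustError, ValueError):
    """Invalid pipeline run configuration."""
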