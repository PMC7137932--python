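"""Exception hierarchy shared across the package."""


class NichepackError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NichepackError):
    """An input table is missing a mandatory column."""


class EmptyInputError(NichepackError):
    """An input table contains no data rows."""


class MetadataError(NichepackError):
    """Site metadata is incomplete or inconsistent with the records."""


class DataError(NichepackError):
    """A value is physically impossible (e.g. non-positive body length)."""


class DimensionError(NichepackError):
    """Requested embedding dimension exceeds what the distances support."""


class PoolError(NichepackError):
    """A species pool is empty or inconsistent."""


class InfeasibleDrawError(NichepackError):
    """A random community larger than its pool was requested."""


class ConstraintError(NichepackError):
    """Hull-constrained pool construction failed (degenerate hull)."""


class ModelError(NichepackError):
    """A statistical model could not be fit (e.g. rank-deficient design)."""


class ConfigError(NichepackError):
    """A configuration value is out of range or internally inconsistent."""
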