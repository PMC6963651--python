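"""Exception hierarchy shared across the pipeline.

Validation failures (bad rows, missing columns, orphan identifiers) are
distinguished from numerical degeneracies (singular covariance, constant
columns) so the CLI can map them to distinct exit codes.
"""


class ForestBefError(Exception):
    """Base class for all package errors."""


class SchemaError(ForestBefError):
    """A table is missing required columns or has an unusable header."""


class ValidationError(ForestBefError):
    """A row violates a field invariant (e.g. non-positive DBH)."""


class CrossReferenceError(ForestBefError):
    """An identifier in one table has no match in another."""


class ConfigurationError(ForestBefError):
    """The run configuration is incomplete or inconsistent."""


class DegenerateDataError(ForestBefError):
    """Data are numerically degenerate for the requested operation."""


class ModelError(ForestBefError):
    """A model specification is invalid (e.g. cyclic path diagram)."""
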