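"""Exception hierarchy for featuregain.

All package-specific failures derive from :class:`FeatureGainError` so callers
can catch one base class; subclasses also derive from the closest builtin
(``ValueError``/``RuntimeError``/``KeyError``) for idiomatic handling.
"""

from __future__ import annotations


class FeatureGainError(Exception):
    """Base class for all featuregain errors."""


class InvalidInputError(FeatureGainError, ValueError):
    """An operation received input violating its preconditions."""


class SpecError(FeatureGainError, ValueError):
    """A network specification is internally inconsistent (shape mismatch etc.)."""


class ConfigError(FeatureGainError, ValueError):
    """A pipeline or cohort configuration is invalid.

    ``keys`` lists the offending configuration keys.
    """

    def __init__(self, message: str, keys: tuple[str, ...] = ()):
        self.keys = tuple(keys)
        if keys:
            message = f"{message} (offending keys: {', '.join(keys)})"
        super().__init__(message)


class UndefinedCorrelationError(FeatureGainError, ValueError):
    """Pearson correlation requested against a constant vector."""


class SelectionError(FeatureGainError, ValueError):
    """Voxel selection against a zero-variance feature."""


class NoiseMatchingError(FeatureGainError, RuntimeError):
    """Noise matching failed for every stimulus in a cell."""


class MissingNoiseKeyError(FeatureGainError, KeyError):
    """A correlation record has no matching noise-baseline record."""


class DegenerateDataError(FeatureGainError, ValueError):
    """A statistical test was handed zero-variance data."""


class AliasingError(FeatureGainError, ValueError):
    """A factorial design has empty or aliased cells; names the cells."""

    def __init__(self, message: str, cells: tuple = ()):
        self.cells = tuple(cells)
        if cells:
            message = f"{message}: {', '.join(map(str, cells))}"
        super().__init__(message)


class DependencyError(FeatureGainError, RuntimeError):
    """A pipeline stage was run before its upstream stage."""


class ConflictError(FeatureGainError, RuntimeError):
    """Stored stage outputs were produced under a different configuration."""
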