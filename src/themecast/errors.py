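"""Exception hierarchy shared across the package."""


class ThemecastError(Exception):
    """Base class for all themecast-specific errors."""


class SchemaError(ThemecastError):
    """An input table is missing a required column or field."""


class ConsistencyError(ThemecastError):
    """Cross-referenced artifacts disagree (e.g. unknown article id)."""


class ParameterError(ThemecastError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyMatrixError(ThemecastError):
    """A term-document matrix would contain no terms at all."""


class TermUniverseError(ThemecastError):
    """Two cluster solutions do not cover the same set of terms."""
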