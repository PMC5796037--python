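"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command-line layer:
``FormatError`` -> 2 (malformed input file), ``ConfigError`` -> 3
(inconsistent configuration), ``StageError`` -> 4 (a pipeline stage failed).
"""


class MirmintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirmintError):
    """An on-disk artifact violates its documented dialect."""


class ConfigError(MirmintError):
    """A configuration object violates its own invariants."""


class StageError(MirmintError):
    """A pipeline stage could not complete."""


class UndefinedCorrelationError(MirmintError):
    """Pearson correlation requested for a constant vector."""
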