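"""Exception hierarchy shared across the package."""


class GutRhythmError(Exception):
    """Base class for all package errors."""


class ParseError(GutRhythmError):
    """A file could not be parsed; message names the file (and line if known)."""


class IntegrityError(GutRhythmError):
    """Cross-referential integrity violated (duplicate/missing/mismatched ids)."""


class ConfigError(GutRhythmError):
    """Invalid configuration value."""


class InsufficientDataError(GutRhythmError):
    """A computation refused because its minimum-data rule is not met."""


class RankDeficiencyError(GutRhythmError):
    """A regression design matrix is rank deficient."""


class StageError(GutRhythmError):
    """A pipeline stage failed; message names the stage and the cause."""
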