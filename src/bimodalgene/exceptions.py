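"""Exception hierarchy for bimodalgene.

All errors raised by the library derive from :class:`BimodalGeneError` so callers
can catch everything with one clause; per-gene pipeline code catches the narrower
types to decide between "skip gene" and "abort run".
"""


class BimodalGeneError(Exception):
    """Base class for all bimodalgene errors."""


class DegenerateInputError(BimodalGeneError):
    """All values identical (or otherwise without usable spread)."""


class InsufficientDataError(BimodalGeneError):
    """Too few observations for the requested statistic."""


class DegenerateGroupError(BimodalGeneError):
    """A two-group comparison received an empty group."""


class ConfigError(BimodalGeneError):
    """Invalid configuration value (e.g. permutation count below the floor)."""


class ParseError(BimodalGeneError):
    """Malformed input file."""


class ValidationError(BimodalGeneError):
    """Input file parsed but failed semantic validation."""


class AlignmentError(BimodalGeneError):
    """Sample identifiers of expression matrix and survival table do not match."""


class EmptyInputError(BimodalGeneError):
    """An operation received an empty matrix or table."""


class ExtrapolationError(BimodalGeneError):
    """Requested sample size outside the range covered by a null table."""
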