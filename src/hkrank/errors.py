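"""Exception hierarchy.

Every error raised on bad user input derives from :class:`HkrankError` so the
command-line layer can catch one type and exit with a stage-tagged message.
"""


class HkrankError(Exception):
    """Base class for all errors raised by hkrank."""


class FormatError(HkrankError):
    """A file does not follow the expected dialect."""


class DuplicateIdentifierError(FormatError):
    """A probe or gene identifier occurs more than once."""


class EmptyInputError(HkrankError):
    """An operation received no usable data."""


class AnnotationError(HkrankError):
    """Sample group labels are missing, unknown, or leave a group empty."""


class MappingError(HkrankError):
    """A probe/ortholog mapping is missing or yields an empty result."""


class InsufficientDataError(HkrankError):
    """Too few values, genes, or samples for the requested statistic."""


class ConfigurationError(HkrankError):
    """Invalid parameter combination (repetitions, top_n, dataset count...)."""


class MissingDataError(HkrankError):
    """A required measurement (e.g. a panel gene's Ct) is absent."""
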