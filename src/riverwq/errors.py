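"""Exception hierarchy for riverwq."""


class RiverWQError(Exception):
    """Base class for all riverwq errors."""


class ConfigurationError(RiverWQError):
    """A standards/weights configuration is inconsistent or incomplete."""


class ValidationError(RiverWQError):
    """A sample record violates a physical or structural invariant."""


class IncompleteIndexError(RiverWQError):
    """An index was requested but a member of its parameter set is missing."""


class ClassificationError(RiverWQError):
    """An index value cannot be assigned a qualitative class."""


class InsufficientDataError(RiverWQError):
    """Too few observations for the requested statistic."""


class FormatError(RiverWQError):
    """An input table violates the expected CSV layout."""
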