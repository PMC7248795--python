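"""Exception hierarchy shared across the package."""


class StimtrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StimtrackError, ValueError):
    """A numeric parameter is outside its valid domain."""


class InvalidInputError(StimtrackError, ValueError):
    """An input object (trace, date, count) violates a precondition."""


class NoCyclesError(StimtrackError):
    """A window contains no supra-threshold contraction cycle."""


class EncodingError(StimtrackError):
    """A session record cannot be represented in the binary layout."""


class CorruptStreamError(StimtrackError):
    """A sync byte stream is malformed (record boundary violation)."""


class IncompleteStreamError(StimtrackError):
    """A sync byte stream ended without a terminator and no timeout."""


class ConfigurationError(StimtrackError):
    """A configuration file or object is inconsistent."""
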