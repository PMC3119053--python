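"""Exception types shared across the pipeline stages."""


class PiebaldNetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PiebaldNetError):
    """An input file could not be parsed; the message names file and line."""


class ConfigurationError(PiebaldNetError):
    """A simulation or pipeline configuration is internally inconsistent."""


class PoolExhaustedError(PiebaldNetError):
    """The candidate control pool ran out during matched selection."""
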