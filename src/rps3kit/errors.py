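"""Exception hierarchy shared by all pipeline stages."""


class Rps3KitError(Exception):
    """Base class for all package errors."""


class InputError(Rps3KitError):
    """An input file or in-memory object violates a stage precondition."""


class ParseError(Rps3KitError):
    """A record in an input file could not be interpreted."""


class ConfigError(Rps3KitError):
    """Configuration is inconsistent with the supplied data."""
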