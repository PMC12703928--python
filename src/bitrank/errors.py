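"""Exception hierarchy shared across the package."""


class BitrankError(Exception):
    """Base class for all errors raised by bitrank."""


class ConfigError(BitrankError, ValueError):
    """Invalid structure parameters (block width, superblock width, ...)."""


class RangeError(BitrankError, IndexError):
    """Query position outside the valid range."""


class AlphabetError(BitrankError, ValueError):
    """Symbol or code outside the configured alphabet."""


class FormatError(BitrankError, ValueError):
    """Malformed input file or serialized container."""
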