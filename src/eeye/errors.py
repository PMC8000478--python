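"""Exception hierarchy shared across the package.

``ConfigurationError`` marks invalid user configuration (CLI exit code 2),
``DataError`` marks invalid or unreadable data (CLI exit code 3).
"""


class EEyeError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(EEyeError):
    """A configuration value violates a precondition."""


class DataError(EEyeError):
    """Input data is missing, malformed, or inconsistent."""


class ImageIOError(DataError):
    """An image file could not be read or has the wrong layout."""
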