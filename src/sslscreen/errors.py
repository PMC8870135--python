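"""Exception hierarchy for the screen-analysis pipeline.

Every stage raises a subclass of :class:`ScreenError` so callers (and the
CLI) can distinguish malformed files, semantically invalid data, failed
quality control, and bad configuration.
"""


class ScreenError(Exception):
    """Base class for all errors raised by sslscreen."""


class FormatError(ScreenError):
    """A file or record does not conform to the expected format."""


class ValidationError(ScreenError):
    """Data is well-formed but semantically invalid (e.g. duplicate IDs)."""


class QCError(ScreenError):
    """A quality-control precondition failed (e.g. a plate lacks controls)."""


class ConfigurationError(ScreenError):
    """A configuration value is missing or out of range."""
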