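"""Exception hierarchy.

All errors raised by mprakit derive from :class:`MprakitError` so callers can
catch the package's failures with a single except clause.
"""


class MprakitError(Exception):
    """Base class for all mprakit errors."""


class ConfigurationError(MprakitError, ValueError):
    """An invalid simulation or analysis configuration."""


class FormatError(MprakitError, ValueError):
    """A malformed input file; the message names the offending row."""


class InputError(MprakitError, ValueError):
    """Invalid values passed to an analysis function."""


class EstimationError(MprakitError, RuntimeError):
    """A model fit could not be carried out on the data provided."""
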