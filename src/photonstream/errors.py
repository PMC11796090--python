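"""Exception hierarchy.

All library-specific failures derive from :class:`PhotonStreamError` so
callers can catch one base class.  File problems split into
:class:`FormatError` (the bytes are not what the format promises) and
:class:`CorruptionError` (the format is recognised but the payload is
inconsistent, e.g. truncated records).
"""


class PhotonStreamError(Exception):
    """Base class for all errors raised by photonstream."""


class ParameterError(PhotonStreamError, ValueError):
    """An argument violates an operation's precondition."""


class CompatibilityError(PhotonStreamError):
    """Two streams cannot be combined (clock or TCSPC geometry differ)."""


class FormatError(PhotonStreamError):
    """A file does not conform to the expected container format."""


class CorruptionError(FormatError):
    """A recognised container carries an inconsistent payload."""


class ConditioningError(PhotonStreamError):
    """A linear-algebra step is too ill-conditioned to be trusted."""


class DegenerateInputError(PhotonStreamError, ValueError):
    """Input is formally valid but carries no usable signal."""
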