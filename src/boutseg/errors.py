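"""Exception hierarchy shared by all boutseg modules."""


class BoutsegError(Exception):
    """Base class for all errors raised by boutseg."""


class ParseError(BoutsegError):
    """A data row could not be parsed; the message names the row number."""


class OrderingError(BoutsegError):
    """Timestamps are not strictly increasing."""


class SchemaError(BoutsegError):
    """Inconsistent column layout (e.g. air column present only sometimes)."""


class ReferenceError_(BoutsegError):
    """A label refers to a point index that does not exist in the trace."""


class ContiguityError(BoutsegError):
    """The labeled index range has gaps."""


class ParameterError(BoutsegError):
    """An argument violates its contract (window size, probabilities, ...)."""


class CapabilityError(BoutsegError):
    """The requested operation needs data the trace does not carry."""


class AlignmentError(BoutsegError):
    """Two per-point structures have mismatched lengths or ranges."""


class InsufficientLabelsError(BoutsegError):
    """Supervised fitting needs at least two labeled points of each state."""


class MomentError(BoutsegError):
    """A state has too few labeled points to estimate mean and variance."""


class DegenerateEmissionError(BoutsegError):
    """All states assign (numerically) zero weight to an observation."""
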