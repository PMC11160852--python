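"""Exception hierarchy.

All package-specific failures derive from :class:`PfanetError` so callers can
catch one base class; each subclass also inherits the matching builtin.
"""


class PfanetError(Exception):
    """Base class for all pfanet errors."""


class DimensionError(PfanetError, ValueError):
    """Array shapes are inconsistent with the declared layer sizes."""


class StateError(PfanetError, RuntimeError):
    """A backward-pass cache was required but not populated."""


class ModeError(PfanetError, RuntimeError):
    """An operation was invoked for an algorithm mode it does not apply to."""


class FormatError(PfanetError, ValueError):
    """A dataset file violates its on-disk format contract."""


class UndefinedAngleError(PfanetError, ValueError):
    """An alignment angle was requested for a zero-norm operand."""


class DivergenceError(PfanetError, RuntimeError):
    """Training produced a non-finite quantity.

    Attributes
    ----------
    layer : int or None
        Index of the layer whose update went non-finite, if known.
    step : int or None
        Global minibatch step at which divergence was detected.
    last_good_epoch : int or None
        Last epoch that completed with a finite loss.
    """

    def __init__(self, message, layer=None, step=None, last_good_epoch=None):
        super().__init__(message)
        self.layer = layer
        self.step = step
        self.last_good_epoch = last_good_epoch
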