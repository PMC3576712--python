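"""Exception hierarchy for dqkin.

All library errors derive from :class:`DQKinError` so callers can catch
the whole family with one clause while still being able to distinguish
singular elements from frame bookkeeping mistakes.
"""


class DQKinError(ValueError):
    """Base class for all dqkin errors."""


class SingularElementError(DQKinError):
    """An element has (near-)zero norm where an inverse or a unit axis is required."""


class NonUnitError(DQKinError):
    """A unit dual quaternion was required but the unitarity residuals are too large."""


class FrameMismatchError(DQKinError):
    """A kinematic state was supplied in the wrong reference frame."""


class UsageError(DQKinError):
    """Invalid argument combination (unknown conjugate kind, bad mode, ...)."""


class DivergenceError(DQKinError):
    """The closed-loop inverse-kinematics iteration diverged."""
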