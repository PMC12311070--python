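"""Exception hierarchy for the tcbc package."""


class TcbcError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TcbcError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDecompositionError(TcbcError):
    """Euler decomposition requested at (or numerically at) gimbal lock."""


class RegistrationFailureError(TcbcError):
    """No optimization start produced a usable objective value."""


class UndefinedEntropyError(TcbcError):
    """Entropy (and hence NMI) is undefined for a degenerate image pair."""


class UndefinedFitError(TcbcError):
    """A regression fit is undefined (e.g. constant predictor)."""


class EmptyReferenceError(TcbcError):
    """Morphological erosion removed every voxel of a reference mask."""


class QuantificationError(TcbcError):
    """An ROI needed for quantification is empty after transformation."""
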