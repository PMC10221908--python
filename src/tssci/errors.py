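"""Exception types raised across the package."""


class TSSCIError(Exception):
    """Base class for all package-specific errors."""


class MalformedTreeError(TSSCIError):
    """Skeleton tree is disconnected, cyclic, or has a bad edge count."""


class DegenerateExtentError(TSSCIError):
    """Coordinate extent is zero, so min-max / centering cannot scale."""


class EmptyGateError(TSSCIError):
    """No keypoint passed the confidence gate; nothing to normalize."""


class InsufficientFramesError(TSSCIError):
    """Fewer frames available than rows requested for sampling."""


class IndeterminateOrientationError(TSSCIError):
    """No frame had confident anchor joints; orientation undecidable."""


class MissingParamsError(TSSCIError):
    """Image lacks the normalization sidecar needed for decoding."""


class DegenerateTrainingError(TSSCIError):
    """Training set lacks the class diversity the model requires."""


class MissingClassError(TSSCIError):
    """An exercise class required by the operation is absent."""


class CannotFitError(TSSCIError):
    """Too few samples to fit the requested distribution."""
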