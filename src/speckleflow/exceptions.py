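"""Exception types shared across the package."""


class SpeckleflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpeckleflowError, ValueError):
    """A physical parameter is outside its admissible domain."""


class InsufficientDataError(SpeckleflowError, ValueError):
    """Not enough samples/records to perform the requested computation."""


class NumericalError(SpeckleflowError, RuntimeError):
    """A quadrature or optimization failed to converge."""


class CalibrationError(SpeckleflowError, RuntimeError):
    """A calibration step (e.g. the coherence-parameter fit) failed."""
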