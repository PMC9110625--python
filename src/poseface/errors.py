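"""Exception hierarchy shared across poseface modules."""


class PosefaceError(Exception):
    """Base class for all poseface errors."""


class InvalidParameterError(PosefaceError, ValueError):
    """A configuration or model parameter is out of its valid range."""


class InvalidInputError(PosefaceError, ValueError):
    """Input data violates a precondition (shape, bounds, homogeneity...)."""


class InsufficientDataError(PosefaceError, ValueError):
    """Not enough observations to pose the problem (e.g. < 3 correspondences)."""


class NotFittedError(PosefaceError, RuntimeError):
    """A model method requiring a completed fit was called before fit()."""
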