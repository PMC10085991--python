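"""Exception types shared across the pipeline."""


class CtdynError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CtdynError, ValueError):
    """A parameter violates a documented precondition."""


class EmptyInputError(CtdynError, ValueError):
    """An operation received no usable data (zero frames, empty path...)."""


class EmptyResultError(CtdynError, ValueError):
    """An operation produced no usable output (e.g. every frame invalid)."""


class EmptyOverlapError(CtdynError, ValueError):
    """Two peak lists share no assigned residues."""


class NoSignalError(CtdynError, RuntimeError):
    """Data carry no fittable signal (flat titration, zero span...)."""


class FitNotConvergedWarning(UserWarning):
    """A nonlinear fit stopped without meeting its convergence criterion."""


class DegenerateFitWarning(UserWarning):
    """A multi-component fit collapsed onto fewer resolvable components."""
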