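"""Exception hierarchy for cortifield."""


class CortifieldError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CortifieldError):
    """A state/trajectory container is missing required datasets or attributes."""


class IntegrityError(CortifieldError):
    """Stored array shapes disagree with the grid metadata."""


class StabilityError(CortifieldError):
    """Requested time step exceeds the linear stability bound."""


class DivergenceError(CortifieldError):
    """The field amplitude blew up during integration."""

    def __init__(self, message, t_blowup=None):
        super().__init__(message)
        self.t_blowup = t_blowup


class SymmetryError(CortifieldError):
    """A matrix required to be Hermitian/symmetric is not."""


class NoLimitCycleError(CortifieldError):
    """Parameters do not admit a finite limit-cycle radius."""


class ConstraintError(CortifieldError):
    """A phase-wave component violates its dispersion constraint."""


class InsufficientDataError(CortifieldError):
    """A trajectory is too short for the requested measurement."""
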