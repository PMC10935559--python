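"""Exception hierarchy for pftwin."""


class PftwinError(Exception):
    """Base class for all pftwin errors."""


class MeshError(PftwinError):
    """Invalid or degenerate triangle mesh."""


class ToleranceError(PftwinError):
    """A requested mesh tolerance could not be reached."""


class DomainError(PftwinError):
    """A query point lies outside the valid domain of a surface."""


class FitError(PftwinError):
    """Least-squares surface fit failed (rank deficiency, bad inputs)."""


class ConfigError(PftwinError):
    """Invalid scenario / simulation configuration."""


class ConvergenceError(PftwinError):
    """An iterative solver (Newton, static equilibrium, step) failed to converge."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history if history is not None else []
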