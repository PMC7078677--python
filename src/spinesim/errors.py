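"""Exception hierarchy for spinesim."""


class SpinesimError(Exception):
    """Base class for all spinesim errors."""


class ConfigurationError(SpinesimError):
    """Invalid model parameters or configuration file."""


class GeometryError(SpinesimError):
    """Degenerate or invalid mesh geometry."""


class ConvergenceError(SpinesimError):
    """An iterative procedure failed to converge within its cap."""


class StabilityError(SpinesimError):
    """Adaptive time-stepping exceeded its recursion-depth cap."""
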