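"""Exception hierarchy for the solver."""


class WillisflowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WillisflowError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class GeometryError(WillisflowError, ValueError):
    """A vessel network or voxel domain violates a structural requirement."""


class ConfigError(WillisflowError, ValueError):
    """A run configuration is inconsistent."""


class SimulationDivergedError(WillisflowError, RuntimeError):
    """The solver produced a nonfinite population or nonpositive density.

    Carries the first offending site (grid coordinates) and the step at
    which the problem was detected.
    """

    def __init__(self, message, site=None, step=None):
        super().__init__(message)
        self.site = site
        self.step = step
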