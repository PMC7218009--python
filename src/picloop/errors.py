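"""Exception hierarchy for the simulator."""


class PicloopError(Exception):
    """Base class for all package errors."""


class SWCParseError(PicloopError):
    """Malformed SWC content; message names the offending line."""


class StructuralError(PicloopError):
    """Morphology violates tree structure (cycles, missing parents, multiple somas)."""


class ParameterError(PicloopError, ValueError):
    """A parameter is outside its allowed domain."""


class EmptyBandError(PicloopError):
    """A requested path-length band intersects no dendritic membrane."""


class ContractError(PicloopError):
    """An operation was called with inputs violating its contract."""


class StateError(PicloopError):
    """Operation requires a state (e.g. calibration) that is not present."""


class IntegrationError(PicloopError):
    """The cable integrator produced a non-finite voltage."""


class CalibrationError(PicloopError):
    """A calibration target could not be reached within bounds/iterations."""
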