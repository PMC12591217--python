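"""Exception hierarchy shared across the simulator.

Exit-code mapping used by the CLI: ConfigError -> 2, ActuationFault and
CompilationError -> 3, everything else -> 1.
"""


class BeadopsError(Exception):
    """Base class for all package errors."""


class ConfigError(BeadopsError):
    """Invalid or missing configuration / layout input."""


class LayoutError(ConfigError):
    """Chip layout violates a structural invariant (overlap, off-lattice)."""


class AddressingError(BeadopsError):
    """Unknown coil id or invalid address-map request."""


class ActuationFault(BeadopsError):
    """A commanded motion is physically inconsistent with the current state
    (motor asked to jump cells, or the force-balance zone contradicts the
    requested operation)."""


class RoutingError(BeadopsError):
    """No path exists between two cells on the coil grid."""


class CompilationError(BeadopsError):
    """A protocol command cannot be compiled to a feasible schedule."""


class StateError(BeadopsError):
    """An operation was applied to chip state that does not admit it."""


class FitError(BeadopsError):
    """Calibration-curve fitting failed (degenerate or insufficient data)."""


class CalibrationError(BeadopsError):
    """Optical calibration is impossible (e.g. zero background intensity)."""


class MeasurementError(BeadopsError):
    """Optical measurement precondition violated (e.g. beads still in the
    detection chamber)."""
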