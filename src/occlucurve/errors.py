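"""Exception hierarchy shared by all occlucurve modules."""


class OccluCurveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OccluCurveError):
    """Invalid run configuration (bad value, unknown key, inconsistent geometry)."""


class DataError(OccluCurveError):
    """Malformed input data (profiles, CSV files, misaligned arrays)."""


class SolverError(OccluCurveError):
    """A contact/equilibrium solve failed to converge."""


class StabilityError(OccluCurveError):
    """A per-cycle surface update exceeded its stability safeguard."""


class SimulationIntegrityError(OccluCurveError):
    """Mesh invariants violated mid-run (e.g. inverted element)."""
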