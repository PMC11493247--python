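"""Exception hierarchy for curvecage."""


class CurveCageError(Exception):
    """Base class for all curvecage errors."""


class BindingError(CurveCageError):
    """Dimension mismatch or invalid harmonic binding."""


class TopologyError(CurveCageError):
    """Mesh/cage connectivity is invalid (non-watertight, isolated vertex...)."""


class GeometryError(CurveCageError):
    """Degenerate geometry (zero-area triangle, self-intersection...)."""


class ContainmentError(CurveCageError):
    """A point that must lie inside a closed surface does not."""


class DiscretizationError(CurveCageError):
    """Grid resolution too low for a well-posed harmonic solve."""


class SolverError(CurveCageError):
    """A linear solve failed or did not reach the requested tolerance."""


class ParameterError(CurveCageError):
    """Invalid user-supplied parameter value."""


class CurveError(CurveCageError):
    """Invalid curve constraint (too few points, duplicates, bad keyframes...)."""


class ConstraintError(CurveCageError):
    """Constraint assembly failed (no curves for a frame, empty point set)."""
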