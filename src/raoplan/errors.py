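"""Exception hierarchy for the planning/evaluation pipeline."""


class RaoplanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RaoplanError):
    """Invalid user-supplied configuration (bad clock step, missing coverage ...)."""


class DegenerateInputError(RaoplanError):
    """Geometric input does not determine the requested object (coplanar sphere
    points, collinear correspondences, collinear APP landmarks ...)."""


class PlanningError(RaoplanError):
    """Virtual osteotomy / reorientation cannot be carried out as requested."""


class InfeasiblePlanError(PlanningError):
    """Reorientation targets unreachable; carries achieved vs target values."""

    def __init__(self, message: str, achieved: dict | None = None,
                 targets: dict | None = None):
        super().__init__(message)
        self.achieved = achieved or {}
        self.targets = targets or {}


class SimulationError(RaoplanError):
    """Intraoperative-confirmation sampler failed (tolerance inconsistent with
    the error model, attempt budget exhausted ...)."""
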