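"""Exception types shared across the pipeline."""


class LutadoseError(Exception):
    """Base class for all package errors."""


class PhantomError(LutadoseError):
    """Invalid phantom specification (organ outside grid, 3D overlap, ...)."""


class GeometryError(LutadoseError):
    """Mismatched image/volume geometry."""


class QuantificationError(LutadoseError):
    """ROI/VOI quantification failure (empty ROI, occluded organ, ...)."""


class FitError(LutadoseError):
    """Time-activity curve fitting failure."""


class NonDecayingCurveError(FitError):
    """Fit converged to a non-decaying curve (lambda_eff <= 0).

    Carries the fitted values instead of silently clamping them.
    """

    def __init__(self, a0: float, lambda_per_h: float):
        self.a0 = a0
        self.lambda_per_h = lambda_per_h
        super().__init__(
            f"fitted curve does not decay: A0={a0:.6g} MBq, "
            f"lambda={lambda_per_h:.6g} h^-1"
        )


class DosimetryError(LutadoseError):
    """Dose calculation failure (non-positive mass, missing S-value, ...)."""


class ScenarioError(LutadoseError):
    """A workflow cannot run on the given study (missing frames, ...)."""


class ConfigError(LutadoseError):
    """Invalid run configuration (unknown key, bad units, ...)."""
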