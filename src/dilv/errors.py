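"""Exception hierarchy for the dilv package."""


class DILVError(Exception):
    """Base class for all dilv errors."""


class InvalidParameterError(DILVError, ValueError):
    """A model or grid parameter violates its validity constraints."""


class DegenerateNormalizationError(DILVError, ValueError):
    """A masked signal has (near-)zero maximum and cannot be normalized.

    Carries the name of the offending model term when raised from the
    waveform models.
    """

    def __init__(self, term: str, maximum: float):
        self.term = term
        self.maximum = maximum
        super().__init__(
            f"degenerate normalization of term {term!r}: "
            f"post-burn-in maximum {maximum:.3e} is too close to zero"
        )


class CouplingViolationError(DILVError, ValueError):
    """Volume and pressure models must share the respiratory frequency."""


class DegenerateFitError(DILVError, ValueError):
    """Regression design is rank deficient (e.g. constant volume, zero flow)."""


class EstimationFailureError(DILVError, RuntimeError):
    """No optimization start converged; diagnostics attached."""


class WaveformFormatError(DILVError, ValueError):
    """A waveform file violates the expected delimited-text format."""


class SegmentationError(DILVError, ValueError):
    """A continuous record could not be split into breaths."""
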