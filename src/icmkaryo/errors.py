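"""Exception hierarchy for the icmkaryo pipeline."""


class IcmError(Exception):
    """Base class for all icmkaryo errors."""


class ValidationError(IcmError):
    """Invalid inputs or parameters (precondition violation)."""


class PlacementError(IcmError):
    """Synthetic metaphase renderer could not place all chromosomes on the canvas."""


class PeakNotFoundError(IcmError):
    """Fewer G0/G1 peaks than expected in a flow-cytometry histogram."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class SegmentationError(IcmError):
    """No segmentable objects in an optical-density map."""


class AxisError(IcmError):
    """Medial axis could not be extracted (disconnected or degenerate mask)."""


class NoConstrictionError(IcmError):
    """Width profile has no detectable primary constriction."""


class CalibrationError(IcmError):
    """Instrument-qualification test could not be evaluated."""


class StageError(IcmError):
    """A pipeline stage failed; carries the stage name for provenance."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
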