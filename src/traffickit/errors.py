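"""Named exception types. Readers reject invalid data instead of coercing it."""


class TraffickitError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(TraffickitError):
    """Intensity image and label mask shapes differ."""


class NonIntegerLabelsError(TraffickitError):
    """Label mask contains values that are not non-negative integers."""


class NoCellsError(TraffickitError):
    """Label mask contains no nonzero labels."""


class EmptyMaskError(TraffickitError):
    """A cell mask has no pixels."""


class MaskOverlapError(TraffickitError):
    """A cell mask overlaps other-cell pixels (or another synthetic cell)."""


class MaskPlacementError(TraffickitError):
    """A synthetic mask would violate radius or border-margin constraints."""


class MissingColumnsError(TraffickitError):
    """A CSV is missing required columns."""


class NonMonotoneTimeError(TraffickitError):
    """Trace timestamps are not strictly increasing."""


class NonPositiveLuminescenceError(TraffickitError):
    """Donor-channel (480 nm) luminescence is zero or negative where a ratio is needed."""


class EmptyBackgroundError(TraffickitError):
    """All background contour bands of a cell are empty (border-proximate cell)."""


class NoBaselineError(TraffickitError):
    """No pre-stimulation timepoints available for baseline correction."""


class NormalizationError(TraffickitError):
    """Experiment-wide normalizer is zero or negative."""


class FitError(TraffickitError):
    """Dose–response fit failed from every starting point."""
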