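"""Exception hierarchy for dscqc.

Every recoverable per-voxel failure has a distinct type so that feature
extraction can convert it into a validity flag with a stable reason string.
"""


class DscQcError(Exception):
    """Base class for all dscqc errors."""


class SeriesTooShortError(DscQcError):
    """Signal-time course has too few dynamics for the operation."""


class NoBolusError(DscQcError):
    """Moving/cumulative means never diverge: no bolus structure found."""


class DegenerateFirstPassError(DscQcError):
    """Baseline end and post-bolus start leave fewer than 3 first-pass dynamics."""


class MinimumAtBoundaryError(DscQcError):
    """First-pass minimum sits at the first or last dynamic of the series."""


class DegenerateBaselineError(DscQcError):
    """Baseline standard deviation is zero; SDNR undefined."""


class FirstPassTooShortError(DscQcError):
    """Fewer than 4 first-pass dynamics: gamma-variate fit underdetermined."""


class NoHalfLevelCrossingError(DscQcError):
    """Signal never re-crosses the half-drop level on one side of the minimum."""


class ZeroSignalDropError(DscQcError):
    """Signal drop is zero (or negative); PSR/FWHM undefined."""


class SingleClassError(DscQcError):
    """Operation requires both classes present."""


class NoPassingExamplesError(DscQcError):
    """Range calibration requires at least one passing example."""


class InsufficientDataError(DscQcError):
    """Not enough data per class for the requested fold count."""


class UnknownFamilyError(DscQcError):
    """Classifier family not in the supported set."""


class LengthMismatchError(DscQcError):
    """Paired rating vectors differ in length."""


class Not4DError(DscQcError):
    """Input volume is not 4-dimensional."""


class TrUnavailableError(DscQcError):
    """Repetition time neither in the volume header nor supplied."""


class SchemaMismatchError(DscQcError):
    """Feature table columns do not match what the model was trained on."""


class InvalidParamsError(DscQcError):
    """Synthetic course parameters violate their invariants."""
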