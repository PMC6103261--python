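"""Exception hierarchy for the eicoquant pipeline."""


class EicoquantError(Exception):
    """Base class for all package-specific errors."""


class TransitionFormatError(EicoquantError):
    """A transition table is malformed (missing column, unparseable field)."""


class LibraryIntegrityError(EicoquantError):
    """Cross-references inside a method library do not resolve."""


class UnknownAnalyteError(EicoquantError, KeyError):
    """An analyte_id is not present in the library."""


class NoInternalStandardError(EicoquantError):
    """The analyte is itself an internal standard and has no IS pairing."""


class SchedulingError(EicoquantError):
    """A transition cannot be scheduled (no expected retention time)."""


class InsufficientDataError(EicoquantError):
    """Too few data points to compute a statistic (e.g. S/N noise estimate)."""


class DegenerateDesignError(EicoquantError):
    """A calibration design cannot support the requested fit."""


class WeightingError(EicoquantError):
    """The requested regression weighting is invalid for the given design."""


class UnquantifiableError(EicoquantError):
    """A sample cannot be quantified (missing or zero-area internal standard)."""
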