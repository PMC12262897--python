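"""Exception hierarchy for the bimm package."""


class BimmError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(BimmError):
    """A cohort table violates its schema or invariants."""


class DegenerateOutcomeError(BimmError):
    """An operation requires both outcome classes but only one is present."""


class PhiUndefinedError(BimmError):
    """The phi coefficient is undefined because a margin of the 2x2 table is zero."""


class CalibrationError(BimmError):
    """Intercept or variance calibration failed to bracket its target."""


class NotConvergedError(BimmError):
    """A fit did not converge and the requested quantity is unreliable."""
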