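"""Exception hierarchy for the pipeline.

All errors raised by sipipe derive from :class:`SipipeError`, so callers can
catch pipeline failures without masking programming errors.
"""


class SipipeError(Exception):
    """Base class for all sipipe errors."""


class GapError(SipipeError):
    """A monthly series has missing or duplicated calendar months."""


class CoverageError(SipipeError):
    """An observation window requires months absent from a series."""


class ValidationError(SipipeError):
    """Input data violate a declared invariant (sign, units, duplicates...)."""


class DegenerateScaleError(SipipeError):
    """The percentage bend scale estimate is zero (too many ties at the median)."""


class DegenerateRangeError(SipipeError):
    """Min-max scaling of a constant vector is undefined."""


class UnstableBootstrapError(SipipeError):
    """More than the tolerated fraction of bootstrap replicates failed."""


class CollinearityError(SipipeError):
    """The regression design matrix is rank deficient."""
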