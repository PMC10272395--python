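"""Exception hierarchy for the gutmr pipeline.

All pipeline-level failures derive from :class:`GutmrError` so callers can
fail soft on a single exposure-outcome pair without masking programming
errors.
"""


class GutmrError(Exception):
    """Base class for all gutmr errors."""


class FormatError(GutmrError):
    """A summary-statistics file does not conform to the expected schema."""


class EmptyInputError(GutmrError):
    """A table is empty after validation, or an operation received no records."""


class ConfigurationError(GutmrError):
    """Inconsistent configuration, e.g. an rsid missing from the LD map."""


class DegenerateInstrumentError(GutmrError):
    """An instrument with a zero SNP-exposure effect cannot form a Wald ratio."""


class InsufficientInstrumentsError(GutmrError):
    """Fewer instruments than the estimator's minimum J."""


class CollinearityError(GutmrError):
    """No variation in the SNP-exposure effects; the Egger fit is rank deficient."""


class ContractViolationError(GutmrError):
    """A mandatory argument (e.g. a resampling seed) was not supplied."""
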