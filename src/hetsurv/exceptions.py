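"""Exception hierarchy shared across the package."""


class HetsurvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HetsurvError):
    """A feature schema is inconsistent or does not match the data."""


class ValidationError(HetsurvError):
    """Input data violates a cohort invariant (e.g. nonpositive time)."""


class EmptyIntersectionError(HetsurvError):
    """No feature is shared by every cohort."""


class MetricUndefinedError(HetsurvError):
    """A metric has no defined value on the given input.

    Raised e.g. when the concordance index has no comparable pair, when the
    events-only RMSE sees zero events, or when an IPCW weight would divide by
    an estimated censoring probability of zero.
    """


class FitFailureError(HetsurvError):
    """A base learner failed to fit; carries the offending spec."""

    def __init__(self, spec, cause):
        self.spec = spec
        self.cause = cause
        super().__init__(f"fit failed for {spec!r}: {cause}")


class EmptyLibraryError(HetsurvError):
    """Model selection discarded every candidate."""
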