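"""Exception hierarchy shared across the pipeline stages."""


class OmsurvError(Exception):
    """Base class for all package errors."""


class SchemaError(OmsurvError):
    """The column-role schema does not match the CSV (missing time/event column, ...)."""


class ValidationError(OmsurvError):
    """Input data violates a structural invariant (duplicate ids, negative time, ...)."""


class EmptyInputError(OmsurvError):
    """A table with zero data rows was supplied."""


class ParameterError(OmsurvError):
    """A parameter is outside its admissible range."""


class UnfitError(OmsurvError):
    """A model cannot be fitted (e.g. no observed events)."""


class ConvergenceError(OmsurvError):
    """Iterative fitting did not converge within the iteration cap.

    Carries the last iterate in ``last_beta``.
    """

    def __init__(self, message, last_beta=None):
        super().__init__(message)
        self.last_beta = last_beta


class CollinearityError(OmsurvError):
    """Rank-deficient design matrix; ``features`` names the collinear columns."""

    def __init__(self, message, features=()):
        super().__init__(message)
        self.features = list(features)


class UndefinedResultError(OmsurvError):
    """The requested statistic is undefined on this input (no comparable pairs, ...)."""
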