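"""Exception and warning hierarchy."""


class LookalikeError(Exception):
    """Base class for all package errors."""


class SchemaError(LookalikeError):
    """A variable, category, or raw code violates the declared schema."""


class ParseError(LookalikeError):
    """Raw input could not be parsed (e.g. non-numeric age)."""


class ModelError(LookalikeError):
    """A model family is incompatible with the data handed to it."""


class SingularDesignError(ModelError):
    """Design matrix is rank deficient. Carries the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class SeparationError(ModelError):
    """Degenerate likelihood: outcome classes are (quasi-)separated."""


class ConvergenceError(ModelError):
    """Iterative fit failed to converge."""


class DonorPoolError(ModelError):
    """Too few observed rows to form a predictive-mean-matching donor pool."""


class AlignmentError(LookalikeError):
    """Two objects that must share structure (columns, coefficient names) do not."""


class ExtrapolationWarning(UserWarning):
    """A recipient category has zero donor support; imputations extrapolate."""
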