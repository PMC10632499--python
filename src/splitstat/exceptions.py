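"""Exception taxonomy shared by all splitstat modules."""


class SplitStatError(Exception):
    """Base class for all splitstat errors."""


class InvalidSizeError(SplitStatError, ValueError):
    """Sample too small (or empty) for the requested operation."""


class InvalidParameterError(SplitStatError, ValueError):
    """A numeric argument is outside its admissible domain."""


class MissingDataError(SplitStatError, ValueError):
    """Input contains missing values; splitstat refuses listwise-silently."""


class DegenerateSplitError(SplitStatError, ValueError):
    """A median split was requested on a constant column."""


class UndefinedCorrelationError(SplitStatError, ValueError):
    """Correlation undefined because a column is constant."""


class CollinearityError(SplitStatError, ValueError):
    """Design matrix rank deficient; offending terms are named."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"design matrix is rank deficient; offending terms: {self.terms}")


class EmptyCellError(SplitStatError, ValueError):
    """A factorial cell has no observations."""


class InvalidFactorError(SplitStatError, ValueError):
    """A factor has fewer than two levels."""


class TermLookupError(SplitStatError, KeyError):
    """A named term/factor/column is not present."""


class IncompleteFitError(SplitStatError, ValueError):
    """A fit lacks the coefficients or covariance entries probing needs."""


class InvalidFitError(SplitStatError, ValueError):
    """Coefficient covariance is not positive (semi)definite."""


class PowerNotAchievableError(SplitStatError, ValueError):
    """Zero effect size: no finite sample size reaches the target power."""


class UndefinedReductionError(SplitStatError, ZeroDivisionError):
    """Percent reduction undefined when the baseline variance explained is 0."""
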