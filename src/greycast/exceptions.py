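"""Exception and warning hierarchy."""


class GreycastError(Exception):
    """Base class for all errors raised by greycast."""


class InvalidSeriesError(GreycastError, ValueError):
    """An input series violates the raw-series contract (non-positive
    values, non-consecutive years, too short)."""


class InvalidSpecError(GreycastError, ValueError):
    """A model or generator specification is out of its valid domain."""


class InternalConsistencyError(GreycastError, ValueError):
    """Intermediate arrays passed between pipeline stages disagree in shape."""


class SingularSystemError(GreycastError, ValueError):
    """The least-squares design matrix is rank deficient."""


class DegenerateModelError(GreycastError, ValueError):
    """The fitted development coefficient is zero, so the whitened
    solution (which divides by it) is undefined."""


class ZeroDenominatorError(GreycastError, ZeroDivisionError):
    """A relative-error denominator is zero for some year."""


class InadmissibleSeriesError(GreycastError, ValueError):
    """Order-ratio admissibility violated and strict checking requested."""


class UndefinedCorrelationError(GreycastError, ValueError):
    """Pearson correlation requested for a zero-variance series."""


class FixtureNotFoundError(GreycastError, KeyError):
    """Requested packaged dataset does not exist."""


class GenerationError(GreycastError, ValueError):
    """A synthetic-series specification produced non-positive values."""


class DataError(GreycastError, ValueError):
    """Malformed input file (CSV/YAML) at the command-line boundary."""


class OrderRatioWarning(UserWarning):
    """Advisory: a series failed the order-ratio admissibility screen."""


class DegeneratePanelWarning(UserWarning):
    """Advisory: all comparison series are identical to the reference, so
    every grey relational coefficient is taken as its limit value 1."""
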