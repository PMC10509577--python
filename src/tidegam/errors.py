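"""Exception hierarchy for the tidegam pipeline.

Every stage raises a subclass of :class:`TidegamError` so callers (CLI,
pipeline driver) can distinguish pipeline failures from programming errors.
"""


class TidegamError(Exception):
    """Base class for all tidegam errors."""


class FormatError(TidegamError):
    """An input file violates its documented column/value contract."""


class EmptyInputError(TidegamError):
    """An input table contains no usable rows."""


class ArgumentError(TidegamError, ValueError):
    """An argument violates a documented precondition."""


class CoverageError(TidegamError):
    """A timestamp falls outside the span covered by the tide table."""


class OrphanRecordError(TidegamError):
    """Sequences exist with no covering camera deployment."""

    def __init__(self, ids):
        self.ids = list(ids)
        super().__init__(
            f"{len(self.ids)} sequence(s) have no covering deployment: "
            f"{self.ids[:10]}{'...' if len(self.ids) > 10 else ''}"
        )


class DegenerateScaleError(TidegamError):
    """A covariate is constant, so it cannot be z-transformed."""


class ModelSpecError(TidegamError):
    """A model specification does not match the data it is applied to."""


class DomainError(TidegamError, ValueError):
    """Covariate values fall outside a spline basis domain."""


class PropagationError(TidegamError):
    """A smooth evaluator returned non-finite values."""
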