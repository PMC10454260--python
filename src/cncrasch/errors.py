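"""Exception hierarchy for cncrasch.

All user-facing validation failures derive from :class:`CncRaschError` so
callers (including the CLI) can catch one base class and report a structured
message.
"""


class CncRaschError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CncRaschError, ValueError):
    """An argument violates a documented precondition."""


class DataValidationError(CncRaschError, ValueError):
    """An input table or file fails structural validation."""


class EstimationError(CncRaschError, RuntimeError):
    """The response data cannot support parameter estimation."""


class UnobservedCategoryError(EstimationError):
    """A rating category never occurs in the data.

    The shared thresholds of the rating-scale model are not identifiable
    when a category is unused.
    """

    def __init__(self, category: int) -> None:
        self.category = category
        super().__init__(
            f"rating category {category} is never observed; shared "
            f"thresholds cannot be estimated"
        )


class ZeroVarianceError(CncRaschError, ValueError):
    """A statistic requiring dispersion was asked of constant data."""
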