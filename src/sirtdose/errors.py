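"""Exception hierarchy for sirtdose."""


class SirtdoseError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SirtdoseError):
    """A phantom or configuration specification violates its invariants."""


class InvalidInputError(SirtdoseError):
    """An image, mask, or table input is unusable (empty, malformed, ...)."""


class GridMismatchError(InvalidInputError):
    """Two volumes that must share a grid do not."""

    def __init__(self, shape_a, shape_b, what="volumes"):
        super().__init__(
            f"{what} live on different grids: {tuple(shape_a)} vs {tuple(shape_b)}"
        )


class UndefinedRatioError(SirtdoseError):
    """A ratio (e.g. T/N) is undefined for the given partition contents."""


class InfeasiblePlanError(SirtdoseError):
    """No finite prescribed activity satisfies the planning constraints."""
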