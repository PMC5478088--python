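"""Exception types raised across the package."""


class InvalidInputError(ValueError):
    """An input violates a documented precondition (shapes, ordering, signs)."""


class DegenerateProblemError(RuntimeError):
    """The stationarity system is rank deficient beyond the SVD truncation
    threshold.

    Attributes
    ----------
    rank_deficit : int
        Number of singular values below the truncation threshold, i.e.
        ``system_size - numerical_rank``.
    """

    def __init__(self, message: str, rank_deficit: int = 0):
        super().__init__(message)
        self.rank_deficit = int(rank_deficit)
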