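"""Exception hierarchy for the agethresh package."""


class AgethreshError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AgethreshError):
    """A census CSV file violates the table dialect or a table invariant."""


class AlignmentError(AgethreshError):
    """A queried age falls strictly inside an age bin.

    Tail counts are only defined at bin boundaries; prorating a bin would
    fabricate equivalence-class sizes, so misaligned queries are an error.
    """


class AggregationError(AgethreshError):
    """Strata cannot be combined because their age bins are incompatible."""


class NoAdmissibleThresholdError(AgethreshError):
    """No age in the search range has a tail count meeting the baseline.

    Carries ``tail_at_floor``: the tail count at the lowest age searched,
    i.e. the largest equivalence class the table can offer in-range.
    """

    def __init__(self, message: str, tail_at_floor: int):
        super().__init__(message)
        self.tail_at_floor = tail_at_floor


class InferenceNotApplicableError(AgethreshError):
    """Longitudinal age deduction cannot run (earlier record may be capped)."""
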