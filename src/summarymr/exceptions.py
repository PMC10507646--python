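"""Exception hierarchy for summarymr."""


class SummaryMRError(Exception):
    """Base class for all summarymr errors."""


class ValidationError(SummaryMRError, ValueError):
    """A record or configuration field violates its invariant.

    Parameters
    ----------
    field : str
        Name of the offending field.
    message : str
        Human-readable description.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FormatError(SummaryMRError, ValueError):
    """An input file does not conform to the expected tabular dialect."""


class NoInstrumentsError(SummaryMRError, ValueError):
    """No SNP survived instrument selection at the given p threshold."""

    def __init__(self, p_threshold: float):
        self.p_threshold = p_threshold
        super().__init__(
            f"no instruments: no SNP with p < {p_threshold:g} in the exposure data"
        )


class DegenerateInstrumentError(SummaryMRError, ValueError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""


class InsufficientSNPsError(SummaryMRError, ValueError):
    """An estimator or test was given fewer SNPs than its minimum."""

    def __init__(self, method: str, minimum: int, got: int):
        self.method = method
        self.minimum = minimum
        self.got = got
        super().__init__(f"{method} requires at least {minimum} SNPs, got {got}")
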