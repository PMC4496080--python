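"""Exception hierarchy shared across the package."""


class OtosrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OtosrError):
    """A table or file does not have the expected layout (e.g. a missing
    required column)."""


class ValidationError(OtosrError):
    """Input values violate a documented invariant (non-monotone distances,
    duplicate ids, out-of-range ratios, ...)."""


class RowError(ValidationError):
    """A single table row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class TooShortError(ValidationError):
    """A transect has too few integration points to segment."""


class CollinearTermsError(OtosrError):
    """The requested design matrix is rank deficient."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(
            "design matrix is rank deficient; collinear terms: "
            + ", ".join(self.terms)
        )


class UndefinedCriterionError(OtosrError):
    """AICc is undefined because n - k - 1 <= 0."""


class SingularGroupError(OtosrError):
    """A discriminant group has fewer than two members, so its variance is
    undefined."""
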