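"""Exception hierarchy.

All input-contract violations raise :class:`ValidationError` (CLI exit code 1);
anything else that goes wrong at run time surfaces as an ordinary exception
(CLI exit code 2).
"""


class BrainMrError(Exception):
    """Base class for all package errors."""


class ValidationError(BrainMrError, ValueError):
    """An input violated a documented precondition."""


class CollinearityError(ValidationError):
    """A design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class AlleleMismatchError(ValidationError):
    """PRS variants that match the genotype panel on neither allele orientation."""

    def __init__(self, variant_ids):
        self.variant_ids = list(variant_ids)
        super().__init__(
            "unresolvable allele mismatch for variants: "
            + ", ".join(map(str, self.variant_ids))
        )


class EmptyResultError(BrainMrError):
    """An operation that requires at least one usable datum received none."""
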