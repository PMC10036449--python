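"""Exception types shared across the package."""

from __future__ import annotations


class NomenclatureError(Exception):
    """Base class for all nomenclature errors."""


class InvariantError(NomenclatureError):
    """A structural invariant of a symbol type was violated.

    Parameters
    ----------
    invariant:
        Short machine-readable name of the violated invariant
        (e.g. ``"allele_letters_require_non_locus_dominance"``).
    message:
        Human-readable explanation.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}")


class ParseError(NomenclatureError):
    """Free text could not be parsed into a symbol type.

    Carries the offending token, an optional linter rule id that the
    malformation corresponds to, and an optional suggested repair.
    """

    def __init__(
        self,
        message: str,
        token: str | None = None,
        rule: str | None = None,
        suggestion: str | None = None,
        offset: int | None = None,
    ):
        self.token = token
        self.rule = rule
        self.suggestion = suggestion
        self.offset = offset
        super().__init__(message)
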