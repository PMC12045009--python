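"""Exception hierarchy for scdecon.

All toolkit errors derive from :class:`ScdeconError` so callers can catch
one base class; the subclasses distinguish label/identity problems from
value problems from file-format problems.
"""


class ScdeconError(Exception):
    """Base class for all scdecon errors."""


class ValidationError(ScdeconError, ValueError):
    """An input value violates a documented invariant."""


class LabelError(ScdeconError, KeyError):
    """Gene, cell-type, or sample labels are missing, duplicated, or mismatched."""

    def __str__(self) -> str:  # KeyError quotes its message; we want it plain
        return self.args[0] if self.args else ""


class FormatError(ScdeconError, ValueError):
    """An on-disk file does not conform to the expected format."""
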