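"""Exception hierarchy for the starcif package.

Every error raised while reading a document carries the 1-based ``line``
number of the offending construct when one is known.
"""

from __future__ import annotations


class CifError(Exception):
    """Base class for all starcif errors."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CifLexicalError(CifError):
    """A character-level problem: unterminated quote or text field, non-ASCII
    byte under strict mode, missing final newline under strict mode."""


class ReservedWordError(CifLexicalError):
    """A STAR reserved word (``stop_`` or ``global_``) that CIF does not use."""


class CifSyntaxError(CifError):
    """A grammar-level problem: dangling tag, value before any tag, tag outside
    a data block, mixed-category loop tags, unterminated save frame."""


class CifShapeError(CifError):
    """A table-shape problem: loop value count not a multiple of the tag
    count, ragged columns, incompatible merge or edit."""


class CifRepresentationError(CifError):
    """A value that cannot be serialized in CIF 1.1 (a multi-line value with a
    line beginning with ``;``)."""


class CifKeyError(CifError, KeyError):
    """An unknown category or keyword, named explicitly."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message flat
        return self.args[0]


class CifPatternError(CifError):
    """An invalid regular expression passed to a search function."""
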