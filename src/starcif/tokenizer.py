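"""Lexical analysis of STAR/CIF/PDBx-mmCIF text.

The tokenizer turns raw document text into a flat sequence of classified
tokens.  It resolves the three lexical layers of the format:

* comments — ``#`` to end of line, recognised only where a new lexeme could
  start (a ``#`` embedded in a bare word is content);
* quoted strings — single or double quotes, where the closing quote counts
  only when followed by whitespace or end of line (CIF 1.1 rule), so
  ``'O'Brien'`` keeps its interior apostrophe;
* semicolon text fields — a line whose first character is ``;`` opens a
  multi-line value terminated by the next line whose first character is
  ``;``; the value is the enclosed lines joined with newlines.

Grammar (which token may follow which) is the reader's concern; this module
only classifies.  CRLF line endings are normalised to LF before scanning.
``stop_`` and ``global_`` are STAR reserved words that CIF does not use; they
are rejected so that corrupt files fail loudly rather than yielding silent
garbage values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

from .errors import CifLexicalError, ReservedWordError

__all__ = [
    "TokenKind",
    "Token",
    "TokenizeOptions",
    "classify_word",
    "tokenize",
]

_WHITESPACE = " \t"


class TokenKind(enum.Enum):
    """Classification of a lexical unit."""

    DATA_HEADING = "data_heading"
    SAVE_HEADING = "save_heading"
    SAVE_END = "save_end"
    LOOP = "loop"
    TAG = "tag"
    VALUE = "value"


@dataclass(frozen=True)
class Token:
    """One lexical unit.

    ``text`` holds the heading name without its ``data_``/``save_`` prefix,
    the tag without its leading underscore, or the unescaped value; source
    case is preserved.  ``line`` is the 1-based line on which the token
    starts; it is non-decreasing across a tokenized sequence.
    """

    kind: TokenKind
    text: str
    line: int


@dataclass(frozen=True)
class TokenizeOptions:
    """Dialect switches for the scanner.

    strict_ascii
        Reject any byte outside the printable-ASCII / whitespace range.  The
        archive format is ASCII; the default is permissive so files with the
        odd accented character in a free-text field still read.
    permit_missing_final_newline
        When False, a non-empty document not ending in a newline is a lexical
        error.  Defaults to True (such files occur in the wild).
    """

    strict_ascii: bool = False
    permit_missing_final_newline: bool = True


def classify_word(word: str) -> TokenKind:
    """Classify a bare whitespace-delimited lexeme.

    The word must not come from inside a quoted string or semicolon text
    field (those are always values).  Reserved-word and heading prefixes are
    matched case-insensitively.

    Raises
    ------
    ReservedWordError
        For the STAR reserved words ``stop_`` and ``global_``.
    """
    lower = word.lower()
    if lower.startswith("data_"):
        return TokenKind.DATA_HEADING
    if lower == "save_":
        return TokenKind.SAVE_END
    if lower.startswith("save_"):
        return TokenKind.SAVE_HEADING
    if lower == "loop_":
        return TokenKind.LOOP
    if lower in ("stop_", "global_"):
        raise ReservedWordError(
            f"reserved STAR word {word!r} is not part of CIF"
        )
    if word.startswith("_"):
        return TokenKind.TAG
    return TokenKind.VALUE


def _make_token(word: str, line: int) -> Token:
    kind = classify_word(word)
    if kind in (TokenKind.DATA_HEADING, TokenKind.SAVE_HEADING):
        text = word[5:]
    elif kind == TokenKind.SAVE_END:
        text = ""
    elif kind == TokenKind.LOOP:
        text = ""
    elif kind == TokenKind.TAG:
        text = word[1:]
    else:
        text = word
    return Token(kind, text, line)


def _check_ascii(text: str) -> None:
    for lineno, line in enumerate(text.split("\n"), start=1):
        for ch in line:
            if not (32 <= ord(ch) < 127 or ch == "\t"):
                raise CifLexicalError(
                    f"non-ASCII or non-printable character {ch!r}", line=lineno
                )


def tokenize(text: str, options: TokenizeOptions | None = None) -> list[Token]:
    """Tokenize a complete CIF/mmCIF document.

    Returns the full token list; an empty document yields an empty list.
    Comments produce no tokens.  Errors report the 1-based line of the
    offending construct.
    """
    return list(iter_tokens(text, options))


def iter_tokens(
    text: str, options: TokenizeOptions | None = None
) -> Iterator[Token]:
    """Streaming form of :func:`tokenize`."""
    opts = options or TokenizeOptions()
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    if opts.strict_ascii:
        _check_ascii(text)
    if (
        not opts.permit_missing_final_newline
        and text
        and not text.endswith("\n")
    ):
        raise CifLexicalError(
            "document does not end with a newline",
            line=text.count("\n") + 1,
        )

    n = len(text)
    i = 0
    line = 1
    at_line_start = True
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            i += 1
            at_line_start = True
            continue
        if ch in _WHITESPACE:
            i += 1
            at_line_start = False
            continue
        if ch == ";" and at_line_start:
            # Multi-line text field: content runs to the next line whose
            # first character is ';'.
            start_line = line
            i += 1
            end = text.find("\n;", i)
            if end == -1:
                raise CifLexicalError(
                    "unterminated semicolon text field", line=start_line
                )
            content = text[i:end]
            yield Token(TokenKind.VALUE, content, start_line)
            line += content.count("\n") + 1
            i = end + 2
            at_line_start = False
            continue
        at_line_start = False
        if ch == "#":
            end = text.find("\n", i)
            i = n if end == -1 else end
            continue
        if ch in "'\"":
            quote = ch
            j = i + 1
            while True:
                if j >= n or text[j] == "\n":
                    raise CifLexicalError(
                        "unterminated quoted string", line=line
                    )
                if text[j] == quote and (
                    j + 1 >= n or text[j + 1] in " \t\n"
                ):
                    break
                j += 1
            yield Token(TokenKind.VALUE, text[i + 1 : j], line)
            i = j + 1
            continue
        j = i
        while j < n and text[j] not in " \t\n":
            j += 1
        word = text[i:j]
        try:
            yield _make_token(word, line)
        except ReservedWordError:
            raise ReservedWordError(
                f"reserved STAR word {word!r} is not part of CIF", line=line
            ) from None
        i = j
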