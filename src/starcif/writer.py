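"""Serialization of documents back to CIF 1.1 / PDBx-mmCIF text.

The writer accepts any of the three representations (CifFile, plain nested
mapping, or the attribute-style wrapper) and emits text that re-parses to a
semantically equal model — the round-trip contract.  Each value is given the
first sufficient form in the order bare -> single-quoted -> double-quoted ->
semicolon text field; minimal quoting keeps rewrites diffable.  A value with
an embedded newline and a line beginning with ";" cannot be represented in
CIF 1.1 and raises CifRepresentationError.

Output style (cosmetic, chosen for familiarity with archive files): a "#"
separator line after the block heading and after every category, key-value
tags padded to a common width within their category, loop columns padded to
the widest cell, rows wrapped at value boundaries when they would exceed
``max_line_length``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import CifRepresentationError
from .model import Category, CifFile, DataBlock, from_plain_mapping
from .tokenizer import TokenKind, tokenize

__all__ = ["WriteOptions", "format_value", "write", "CifFileWriter"]

# Characters that may not start a bare token: quotes and '_' would be
# re-tokenized as something else; '#' would start a comment; ';' could open
# a text field at line start; '$' is a STAR frame reference.
_FORBIDDEN_LEAD = "'\"_#$;"
_WS = (" ", "\t", "\n")


@dataclass(frozen=True)
class WriteOptions:
    """Formatting knobs.

    max_line_length
        Hard wrap limit (archive files use up to 2048 characters); lines
        inside semicolon text fields may exceed it when reproducing long
        source lines.
    align_loop_columns
        Pad loop cells to their column's widest value.
    preserve_category_order
        Emit categories in model (parse) order; there is no re-sorting
        alternative implemented, the flag exists so callers can assert the
        behaviour they rely on.
    """

    max_line_length: int = 2048
    align_loop_columns: bool = True
    preserve_category_order: bool = True

    def __post_init__(self):
        if self.max_line_length < 80:
            raise ValueError("max_line_length must be at least 80")


def _bare_ok(value: str) -> bool:
    if not value:
        return False
    if any(ch in value for ch in _WS):
        return False
    if value[0] in _FORBIDDEN_LEAD:
        return False
    lower = value.lower()
    if lower in ("loop_", "stop_", "global_"):
        return False
    if lower.startswith(("data_", "save_")):
        return False
    return True


def _quotable(value: str, quote: str) -> bool:
    if "\n" in value:
        return False
    # The closing quote is recognised only before whitespace/EOL, so the
    # quoted form is ambiguous iff the value contains quote+whitespace or
    # would place a quote directly before the real terminator... the latter
    # is fine (quote at the very end still closes correctly after it).
    for i, ch in enumerate(value):
        if ch == quote and (i + 1 == len(value) or value[i + 1] in " \t"):
            if i + 1 != len(value):
                return False
    return True


def _text_field(value: str) -> str:
    lines = value.split("\n")
    if any(line.startswith(";") for line in lines):
        raise CifRepresentationError(
            "value has a line beginning with ';' and cannot be written "
            "as a CIF 1.1 text field"
        )
    return "\n;" + value + "\n;\n"


def format_value(value: str, max_inline: int | None = None) -> str:
    """Serialize one value with minimal sufficient quoting.

    Returns an inline fragment, or a text-field fragment beginning with a
    newline (``"\\n;…\\n;\\n"``).  ``max_inline`` demotes an over-long inline
    form to a text field when one is representable.  Tokenizing the result
    always yields exactly one VALUE token whose text equals ``value``.
    """
    value = str(value)
    candidate = None
    if _bare_ok(value):
        candidate = value
    elif _quotable(value, "'"):
        candidate = f"'{value}'"
    elif _quotable(value, '"'):
        candidate = f'"{value}"'
    if candidate is not None:
        if max_inline is not None and len(candidate) > max_inline:
            try:
                return _text_field(value)
            except CifRepresentationError:
                return candidate  # over-long but correct; better than failing
        return candidate
    return _text_field(value)


def _is_text_field(fragment: str) -> bool:
    return fragment.startswith("\n;")


class _Emitter:
    def __init__(self, options: WriteOptions):
        self.opts = options
        self.parts: list[str] = []

    def line(self, text: str = "") -> None:
        self.parts.append(text + "\n")

    def raw(self, text: str) -> None:
        self.parts.append(text)

    def text(self) -> str:
        return "".join(self.parts)


def _tag(cat: Category, keyword: str) -> str:
    if cat.is_plain:
        return f"_{cat.name}"
    return f"_{cat.name}.{keyword}"


def _emit_key_value(cat: Category, em: _Emitter) -> None:
    opts = em.opts
    tags = {kw: _tag(cat, kw) for kw in cat.keywords}
    width = max(len(t) for t in tags.values())
    for kw in cat.keywords:
        value = cat[kw][0]
        budget = opts.max_line_length - width - 1
        frag = format_value(value, max_inline=max(budget, 1))
        tag = tags[kw]
        if _is_text_field(frag):
            em.raw(tag + frag)
        elif len(tag) + 1 + len(frag) > opts.max_line_length:
            em.line(tag)
            em.line(frag)
        else:
            em.line(f"{tag.ljust(width)} {frag}")


def _emit_loop(cat: Category, em: _Emitter) -> None:
    opts = em.opts
    em.line("loop_")
    for kw in cat.keywords:
        em.line(_tag(cat, kw))
    columns = cat.columns
    n_cols = len(cat.keywords)
    frags: list[list[str]] = []
    for kw in cat.keywords:
        frags.append(
            [
                format_value(v, max_inline=opts.max_line_length)
                for v in columns[kw]
            ]
        )
    widths = [0] * n_cols
    if opts.align_loop_columns:
        for c in range(n_cols):
            inline = [f for f in frags[c] if not _is_text_field(f)]
            widths[c] = max((len(f) for f in inline), default=0)
    for r in range(cat.row_count):
        current = ""
        for c in range(n_cols):
            frag = frags[c][r]
            if _is_text_field(frag):
                if current:
                    em.line(current.rstrip())
                    current = ""
                em.raw(frag[1:])  # already ends with newline
                continue
            cell = frag.ljust(widths[c]) if opts.align_loop_columns else frag
            joined = cell if not current else f"{current} {cell}"
            if current and len(joined) > opts.max_line_length:
                em.line(current.rstrip())
                current = cell
            else:
                current = joined
        if current:
            em.line(current.rstrip())


def _emit_category(cat: Category, em: _Emitter) -> None:
    if cat.is_loop:
        _emit_loop(cat, em)
    else:
        _emit_key_value(cat, em)
    em.line("#")


def _emit_block_body(block: DataBlock, em: _Emitter) -> None:
    for cat in block:
        _emit_category(cat, em)


def _emit_block(block: DataBlock, em: _Emitter) -> None:
    em.line(f"data_{block.id}")
    em.line("#")
    _emit_block_body(block, em)
    for name, frame in block.save_frames.items():
        em.line(f"save_{name}")
        _emit_block_body(frame, em)
        em.line("save_")
        em.line("#")


def _coerce(document) -> CifFile:
    if isinstance(document, CifFile):
        return document
    if hasattr(document, "to_plain_mapping") and not isinstance(
        document, Mapping
    ):
        return from_plain_mapping(document.to_plain_mapping())
    if isinstance(document, Mapping):
        return from_plain_mapping(document)
    raise TypeError(
        f"cannot serialize a {type(document).__name__}; expected a CifFile, "
        "a plain mapping or a wrapper"
    )


def write(document, sink=None, options: WriteOptions | None = None) -> str:
    """Serialize ``document`` and return the text.

    ``document`` may be a CifFile, the plain nested mapping, or a
    CifWrapper.  ``sink`` may be a path (gzip-compressed when it ends in
    ".gz") or a file-like object; when None the text is only returned.
    """
    opts = options or WriteOptions()
    cif = _coerce(document)
    em = _Emitter(opts)
    for block in cif:
        _emit_block(block, em)
    text = em.text()
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            path = Path(sink)
            if path.suffix == ".gz":
                with gzip.open(path, "wt", encoding="utf-8") as fh:
                    fh.write(text)
            else:
                path.write_text(text, encoding="utf-8")
    return text


class CifFileWriter:
    """Object-style facade: a writer bound to a sink and options."""

    def __init__(self, sink=None, options: WriteOptions | None = None):
        self.sink = sink
        self.options = options or WriteOptions()

    def write(self, document) -> str:
        return write(document, self.sink, self.options)
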