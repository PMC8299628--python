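"""Grammar layer: token stream -> CifFile, with category filtering.

The grammar is small: a ``data_`` heading opens a block; a tag followed by a
value adds a key-value item (the tag splits at the FIRST period into
category and keyword; a period-less plain-CIF tag such as ``_cell_length_a``
becomes a synthetic one-keyword category named after the whole tag);
``loop_`` followed by tags from a single category and then a run of values
populates a tabular category with one row per tag-count values; ``save_``
headings delimit save frames whose interior follows the same grammar.

Category filtering (ONLY / IGNORE) skips unwanted categories while parsing:
their values are counted and discarded, never stored, which is what makes
selective extraction from coordinate-heavy entry files cheap.  Filtering
applies inside save frames too.
"""

from __future__ import annotations

import enum
import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import CifShapeError, CifSyntaxError
from .model import (
    Category,
    CifFile,
    DataBlock,
    from_plain_mapping,
    to_plain_mapping,
)
from .tokenizer import Token, TokenKind, TokenizeOptions, iter_tokens
from .wrapper import CifWrapper

logger = logging.getLogger(__name__)

__all__ = [
    "FilterMode",
    "CategoryFilter",
    "ParseDiagnostics",
    "Representation",
    "parse",
    "read",
    "read_text",
    "read_file",
    "CifFileReader",
]


class FilterMode(enum.Enum):
    ALL = "all"
    ONLY = "only"
    IGNORE = "ignore"


@dataclass(frozen=True)
class CategoryFilter:
    """Which categories to materialize while parsing.

    ALL keeps everything; ONLY keeps just the named categories; IGNORE
    drops the named ones.  Names compare case-insensitively.
    """

    mode: FilterMode = FilterMode.ALL
    names: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "names", frozenset(n.lower() for n in self.names)
        )
        if self.mode == FilterMode.ALL and self.names:
            raise ValueError("an ALL filter must not name categories")

    @classmethod
    def all(cls) -> "CategoryFilter":
        return cls()

    @classmethod
    def only(cls, *names: str) -> "CategoryFilter":
        return cls(FilterMode.ONLY, frozenset(names))

    @classmethod
    def ignore(cls, *names: str) -> "CategoryFilter":
        return cls(FilterMode.IGNORE, frozenset(names))

    def admits(self, category_name: str) -> bool:
        if self.mode == FilterMode.ALL:
            return True
        member = category_name.lower() in self.names
        return member if self.mode == FilterMode.ONLY else not member


ALL_CATEGORIES = CategoryFilter.all()


@dataclass
class ParseDiagnostics:
    """Counts and warnings accumulated during a parse.

    ``discarded_values`` counts values belonging to filtered-out categories;
    they are never stored in the returned model.
    """

    warnings: list[tuple[int, str]] = field(default_factory=list)
    block_count: int = 0
    category_count: int = 0
    row_total: int = 0
    discarded_values: int = 0

    def warn(self, line: int, message: str) -> None:
        self.warnings.append((line, message))
        logger.warning("line %d: %s", line, message)


class Representation(enum.Enum):
    """Output form of :func:`read`: nested dictionaries, an attribute-style
    searchable view, or the mutable CifFile model."""

    PLAIN = "plain"
    WRAPPED = "wrapped"
    MODEL = "model"


def _split_tag(tag: str) -> tuple[str, str, bool]:
    """(category, keyword, is_plain) from a tag with the underscore already
    stripped.  Splits at the first period; period-less tags name a synthetic
    category whose implicit keyword equals the category name."""
    if "." in tag:
        cat, kw = tag.split(".", 1)
        return cat, kw, False
    return tag, tag, True


class _Peekable:
    def __init__(self, tokens: Iterable[Token]):
        self._it = iter(tokens)
        self._buf: list[Token] = []
        self.last_line = 1

    def peek(self) -> Token | None:
        if not self._buf:
            try:
                self._buf.append(next(self._it))
            except StopIteration:
                return None
        return self._buf[0]

    def next(self) -> Token | None:
        tok = self.peek()
        if tok is not None:
            self._buf.pop(0)
            self.last_line = tok.line
        return tok


def _unique_block_id(cif: CifFile, block_id: str) -> str:
    if block_id not in cif:
        return block_id
    n = 2
    while f"{block_id}_{n}" in cif:
        n += 1
    return f"{block_id}_{n}"


def _merge_category(
    target: DataBlock,
    name: str,
    columns: dict[str, list[str]],
    is_loop: bool,
    is_plain: bool,
    line: int,
    diag: ParseDiagnostics,
) -> None:
    """Add a parsed category to a block, merging with an existing category
    of the same name.

    Merge rules: disjoint keywords with matching row counts gain columns
    (the normal accumulation of key-value items); identical keyword lists
    append rows (split loops in hand-edited files); a duplicate keyword in
    an otherwise key-value merge overwrites with a warning; anything else is
    a shape error.
    """
    existing = target.get_category(name)
    if existing is None:
        cat = Category(name, columns, is_loop=is_loop, is_plain=is_plain)
        target.add_category(cat)
        diag.category_count += 1
        diag.row_total += cat.row_count
        return

    new_rows = len(next(iter(columns.values())))
    existing_lower = {k.lower() for k in existing.keywords}
    incoming_lower = [k.lower() for k in columns]
    if (is_loop or existing.is_loop) and incoming_lower == [
        k.lower() for k in existing.keywords
    ]:
        # Split loop: same keywords, append rows.
        merged = {
            kw: existing[kw] + columns[orig]
            for kw, orig in zip(existing.keywords, columns)
        }
        cat = Category(name, merged, is_loop=True, is_plain=existing.is_plain)
        target.remove_category(name)
        target.add_category(cat)
        diag.row_total += new_rows
        diag.warn(line, f"category {name!r} restated; rows appended")
        return

    if new_rows != existing.row_count:
        raise CifShapeError(
            f"category {name!r} restated with {new_rows} rows, "
            f"previously {existing.row_count}",
            line=line,
        )
    for kw, col in columns.items():
        if kw.lower() in existing_lower:
            diag.warn(
                line,
                f"duplicate item {name}.{kw}; last value kept",
            )
        existing.set_column(kw, col)
    if is_loop:
        existing.is_loop = True


def parse(
    tokens: Iterable[Token],
    category_filter: CategoryFilter = ALL_CATEGORIES,
) -> tuple[CifFile, ParseDiagnostics]:
    """Parse a token stream into a CifFile plus diagnostics.

    Accepts any iterable of tokens (a generator works; filtered-out values
    are discarded as they stream past).  Raises CifSyntaxError or
    CifShapeError with the offending line on malformed input.
    """
    stream = _Peekable(tokens)
    cif = CifFile()
    diag = ParseDiagnostics()
    block: DataBlock | None = None
    frame: DataBlock | None = None
    frame_start = 0

    def target() -> DataBlock:
        return frame if frame is not None else block  # type: ignore[return-value]

    while True:
        tok = stream.next()
        if tok is None:
            break
        if tok.kind == TokenKind.DATA_HEADING:
            if frame is not None:
                raise CifSyntaxError(
                    f"save frame {frame.id!r} not terminated before new "
                    "data block",
                    line=tok.line,
                )
            block_id = tok.text
            if block_id == "":
                diag.warn(tok.line, "data block with empty id")
            unique = _unique_block_id(cif, block_id)
            if unique != block_id:
                diag.warn(
                    tok.line,
                    f"duplicate block id {block_id!r}; renamed to {unique!r}",
                )
            block = cif.new_block(unique)
            diag.block_count += 1
        elif tok.kind == TokenKind.SAVE_HEADING:
            if block is None:
                raise CifSyntaxError(
                    "save frame outside any data block", line=tok.line
                )
            if frame is not None:
                raise CifSyntaxError(
                    "nested save frames are not allowed", line=tok.line
                )
            frame = DataBlock(tok.text)
            frame_start = tok.line
        elif tok.kind == TokenKind.SAVE_END:
            if frame is None:
                raise CifSyntaxError(
                    "save_ terminator without an open save frame",
                    line=tok.line,
                )
            block.add_save_frame(frame)  # type: ignore[union-attr]
            frame = None
        elif tok.kind == TokenKind.TAG:
            if block is None:
                raise CifSyntaxError(
                    f"data item _{tok.text} outside any data block",
                    line=tok.line,
                )
            nxt = stream.peek()
            if nxt is None or nxt.kind != TokenKind.VALUE:
                raise CifSyntaxError(
                    f"tag _{tok.text} has no value", line=tok.line
                )
            value = stream.next()
            cat, kw, is_plain = _split_tag(tok.text)
            if not category_filter.admits(cat):
                diag.discarded_values += 1
                continue
            _merge_category(
                target(), cat, {kw: [value.text]}, False, is_plain,
                tok.line, diag,
            )
        elif tok.kind == TokenKind.LOOP:
            _parse_loop(stream, tok.line, block, target, category_filter, diag)
        else:  # VALUE
            raise CifSyntaxError(
                f"value {tok.text!r} appears before any tag", line=tok.line
            )

    if frame is not None:
        raise CifSyntaxError(
            f"save frame {frame.id!r} not terminated at end of input",
            line=frame_start,
        )
    return cif, diag


def _parse_loop(
    stream: _Peekable,
    loop_line: int,
    block: DataBlock | None,
    target,
    category_filter: CategoryFilter,
    diag: ParseDiagnostics,
) -> None:
    if block is None:
        raise CifSyntaxError("loop_ outside any data block", line=loop_line)
    tags: list[tuple[str, str, bool]] = []
    tag_line = loop_line
    while True:
        nxt = stream.peek()
        if nxt is not None and nxt.kind == TokenKind.TAG:
            stream.next()
            tag_line = nxt.line
            tags.append(_split_tag(nxt.text))
        else:
            break
    if not tags:
        raise CifSyntaxError("loop_ with no tags", line=loop_line)
    cat = tags[0][0]
    for other_cat, _, _ in tags[1:]:
        if other_cat.lower() != cat.lower():
            raise CifSyntaxError(
                f"loop mixes categories {cat!r} and {other_cat!r}",
                line=tag_line,
            )
    admitted = category_filter.admits(cat)
    k = len(tags)
    columns: list[list[str]] = [[] for _ in range(k)] if admitted else []
    count = 0
    while True:
        nxt = stream.peek()
        if nxt is None or nxt.kind != TokenKind.VALUE:
            break
        stream.next()
        if admitted:
            columns[count % k].append(nxt.text)
        else:
            diag.discarded_values += 1
        count += 1
    if count == 0:
        raise CifSyntaxError(
            f"loop over category {cat!r} has no values", line=loop_line
        )
    if count % k != 0:
        raise CifShapeError(
            f"loop over category {cat!r} has {count} values for {k} tags "
            f"({count} % {k} != 0)",
            line=loop_line,
        )
    if admitted:
        _merge_category(
            target(),
            cat,
            {kw: col for (_, kw, _), col in zip(tags, columns)},
            True,
            tags[0][2],
            loop_line,
            diag,
        )


# -- high-level reading -----------------------------------------------------


def _source_to_text(source) -> tuple[str, str | None]:
    """Resolve a text / path / file-object source to (document text, name)."""
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        return data, getattr(source, "name", None)
    if isinstance(source, Path):
        return _read_path(source)
    if isinstance(source, str):
        looks_like_path = "\n" not in source and (
            os.path.exists(source)
            or source.endswith((".cif", ".cif.gz", ".gz", ".mmcif"))
        )
        if looks_like_path:
            return _read_path(Path(source))
        return source, None
    raise TypeError(f"cannot read from {type(source).__name__}")


def _read_path(path: Path) -> tuple[str, str]:
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return fh.read(), str(path)
    return path.read_text(encoding="utf-8"), str(path)


def read_text(
    text: str,
    representation: Representation = Representation.MODEL,
    category_filter: CategoryFilter = ALL_CATEGORIES,
    tokenize_options: TokenizeOptions | None = None,
    with_diagnostics: bool = False,
):
    """Parse document text into the requested representation."""
    cif, diag = parse(
        iter_tokens(text, tokenize_options), category_filter
    )
    if representation == Representation.MODEL:
        result = cif
    elif representation == Representation.PLAIN:
        result = to_plain_mapping(cif)
    elif representation == Representation.WRAPPED:
        result = CifWrapper(to_plain_mapping(cif))
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return (result, diag) if with_diagnostics else result


def read_file(
    path,
    representation: Representation = Representation.MODEL,
    category_filter: CategoryFilter = ALL_CATEGORIES,
    tokenize_options: TokenizeOptions | None = None,
    with_diagnostics: bool = False,
):
    """Read a CIF/mmCIF file (gzip-compressed when the path ends in .gz)."""
    text, name = _read_path(Path(path))
    out = read_text(
        text, representation, category_filter, tokenize_options,
        with_diagnostics=True,
    )
    result, diag = out
    if isinstance(result, CifFile):
        result.source_name = name
    return (result, diag) if with_diagnostics else result


def read(
    source,
    representation: Representation = Representation.MODEL,
    category_filter: CategoryFilter = ALL_CATEGORIES,
    tokenize_options: TokenizeOptions | None = None,
    with_diagnostics: bool = False,
):
    """Read from document text, a file path or an open file object.

    A string is treated as a path when it contains no newline and either
    exists on disk or carries a CIF-ish extension; otherwise it is taken as
    document text (use read_text/read_file to be explicit).
    """
    text, name = _source_to_text(source)
    out = read_text(
        text, representation, category_filter, tokenize_options,
        with_diagnostics=True,
    )
    result, diag = out
    if isinstance(result, CifFile) and name:
        result.source_name = name
    return (result, diag) if with_diagnostics else result


class CifFileReader:
    """Thin object-style facade over :func:`read` for callers that prefer a
    configured reader instance."""

    def __init__(
        self,
        category_filter: CategoryFilter = ALL_CATEGORIES,
        tokenize_options: TokenizeOptions | None = None,
    ):
        self.category_filter = category_filter
        self.tokenize_options = tokenize_options

    def read(
        self, source, representation: Representation = Representation.MODEL
    ):
        return read(
            source,
            representation,
            self.category_filter,
            self.tokenize_options,
        )
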