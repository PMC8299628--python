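"""In-memory document model: CifFile -> DataBlock -> Category.

Values are stored verbatim as strings, including the null conventions "."
(inapplicable) and "?" (unknown); the format is typeless at the syntax level
and any numeric or dictionary-aware interpretation belongs to higher layers.

A Category is a named table: an ordered list of keywords, one equal-length
column of value strings per keyword, and an ``is_loop`` flag distinguishing
the tabular form (written with ``loop_``) from the key-value form (exactly
one row, written as inline tag/value lines).  Category and keyword lookup is
case-insensitive throughout, while source spelling is preserved.

The plain-mapping representation mirrors the file hierarchy as nested
dictionaries: block id -> category name -> keyword -> value, where a
key-value item maps to a single string and a loop column maps to a list of
strings.  It is lossless with respect to values and lossy with respect to
source formatting, and is JSON-serializable by construction.
"""

from __future__ import annotations

import enum
import re
from typing import Iterable, Iterator, Mapping

from .errors import CifKeyError, CifPatternError, CifShapeError

__all__ = [
    "Category",
    "DataBlock",
    "CifFile",
    "SpecialValue",
    "classify_value",
    "match_indices",
    "to_plain_mapping",
    "from_plain_mapping",
    "semantically_equal",
]

INAPPLICABLE = "."
UNKNOWN = "?"


class SpecialValue(enum.Enum):
    """CIF null conventions."""

    NONE = "none"
    INAPPLICABLE = INAPPLICABLE
    UNKNOWN = UNKNOWN


def classify_value(text: str) -> SpecialValue:
    """Classify a value string under the CIF null conventions.

    Exactly "." is inapplicable and exactly "?" is unknown; everything else,
    including quoted source spellings of those characters, is an ordinary
    value (quoting is resolved before values reach the model, so a quoted
    '.' arrives here as the one-character string and is treated as null —
    the conventional archive reading).
    """
    if text == INAPPLICABLE:
        return SpecialValue.INAPPLICABLE
    if text == UNKNOWN:
        return SpecialValue.UNKNOWN
    return SpecialValue.NONE


def match_indices(
    values: Iterable[str], pattern: str, as_regex: bool = False
) -> list[int]:
    """Indices (ascending, 0-based) of values matching ``pattern``.

    Exact mode compares full strings; regex mode uses search semantics
    (a match anywhere in the value).
    """
    if as_regex:
        try:
            prog = re.compile(pattern)
        except re.error as exc:
            raise CifPatternError(f"invalid regex {pattern!r}: {exc}") from exc
        return [i for i, v in enumerate(values) if prog.search(v)]
    return [i for i, v in enumerate(values) if v == pattern]


class Category:
    """A named table of value strings.

    Parameters
    ----------
    name
        Category name, no leading underscore and no period.
    columns
        Mapping keyword -> list of value strings; insertion order defines
        keyword order.  All columns must have the same length R >= 1.
    is_loop
        True for the tabular form; the key-value form requires R == 1.
    is_plain
        True when the category came from a period-less plain-CIF tag such as
        ``_cell_length_a``; the single keyword then equals the category name
        and the writer restores the ``_tag value`` spelling.
    """

    def __init__(
        self,
        name: str,
        columns: Mapping[str, list[str]],
        is_loop: bool = False,
        is_plain: bool = False,
    ):
        if not name:
            raise ValueError("category name must be non-empty")
        if not columns:
            raise ValueError(f"category {name!r} must have at least one keyword")
        self.name = name
        self.is_loop = bool(is_loop)
        self.is_plain = bool(is_plain)
        self._columns: dict[str, list[str]] = {}
        self._by_lower: dict[str, str] = {}
        length = None
        for kw, col in columns.items():
            col = list(col)
            if not col:
                raise CifShapeError(
                    f"column {kw!r} of category {name!r} is empty"
                )
            if length is None:
                length = len(col)
            elif len(col) != length:
                raise CifShapeError(
                    f"ragged columns in category {name!r}: "
                    f"{kw!r} has {len(col)} values, expected {length}"
                )
            if kw.lower() in self._by_lower:
                raise ValueError(
                    f"duplicate keyword {kw!r} in category {name!r}"
                )
            self._columns[kw] = col
            self._by_lower[kw.lower()] = kw
        if not self.is_loop and length != 1:
            raise CifShapeError(
                f"key-value category {name!r} must have exactly one row, "
                f"got {length}"
            )

    # -- introspection -----------------------------------------------------

    @property
    def keywords(self) -> list[str]:
        return list(self._columns)

    @property
    def columns(self) -> dict[str, list[str]]:
        return {kw: list(col) for kw, col in self._columns.items()}

    @property
    def row_count(self) -> int:
        return len(next(iter(self._columns.values())))

    def __len__(self) -> int:
        return self.row_count

    def __contains__(self, keyword: str) -> bool:
        return keyword.lower() in self._by_lower

    def _resolve(self, keyword: str) -> str:
        try:
            return self._by_lower[keyword.lower()]
        except KeyError:
            raise CifKeyError(
                f"category {self.name!r} has no keyword {keyword!r} "
                f"(available: {', '.join(self._columns)})"
            ) from None

    def __getitem__(self, keyword: str) -> list[str]:
        return list(self._columns[self._resolve(keyword)])

    def item_values(self, keyword: str) -> list[str]:
        """Full column for ``keyword`` in row order (length 1 for the
        key-value form)."""
        return self[keyword]

    def rows(self) -> Iterator[dict[str, str]]:
        """Row-wise view: one mapping keyword -> value per row, keyword
        order preserved."""
        kws = self.keywords
        for r in range(self.row_count):
            yield {kw: self._columns[kw][r] for kw in kws}

    def search(
        self, keyword: str, pattern: str, as_regex: bool = False
    ) -> list[tuple[int, dict[str, str]]]:
        """Rows whose ``keyword`` value matches ``pattern``.

        Returns (row-index, row-mapping) pairs with ascending 0-based
        indices.  Exact mode is full-string equality; regex mode is
        ``re.search`` semantics.
        """
        column = self._columns[self._resolve(keyword)]
        hits = match_indices(column, pattern, as_regex)
        return [
            (i, {kw: self._columns[kw][i] for kw in self._columns})
            for i in hits
        ]

    # -- mutation ----------------------------------------------------------

    def set_column(self, keyword: str, values: list[str]) -> None:
        """Replace or append the column for ``keyword``.

        The new column must match the current row count, unless this
        category consists of only this keyword (then the row count may
        change).
        """
        values = [str(v) for v in values]
        if not values:
            raise CifShapeError(
                f"cannot set empty column {keyword!r} on category {self.name!r}"
            )
        existing = self._by_lower.get(keyword.lower())
        only_this = existing is not None and len(self._columns) == 1
        if len(values) != self.row_count and not only_this:
            raise CifShapeError(
                f"column {keyword!r} has {len(values)} values but category "
                f"{self.name!r} has {self.row_count} rows"
            )
        if existing is not None:
            self._columns[existing] = values
        else:
            self._columns[keyword] = values
            self._by_lower[keyword.lower()] = keyword
        if len(values) > 1:
            self.is_loop = True

    def equals(self, other: "Category") -> bool:
        """Semantic equality: same name (case-insensitive), same keyword
        list, same value lists.  Loop flag and formatting are excluded."""
        return (
            self.name.lower() == other.name.lower()
            and [k.lower() for k in self.keywords]
            == [k.lower() for k in other.keywords]
            and all(
                self._columns[k] == other[k] for k in self.keywords
            )
        )

    def copy(self) -> "Category":
        return Category(self.name, self._columns, self.is_loop, self.is_plain)

    def __repr__(self) -> str:
        kind = "loop" if self.is_loop else "key-value"
        return (
            f"<Category {self.name!r} ({kind}): "
            f"{len(self._columns)} keywords x {self.row_count} rows>"
        )


class DataBlock:
    """An ordered collection of categories plus optional save frames.

    Save frames (used by CIF dictionaries and the Chemical Component
    Dictionary) are themselves DataBlock instances; ordinary PDB entry files
    have none.
    """

    def __init__(self, block_id: str):
        self.id = block_id
        self._categories: dict[str, Category] = {}  # keyed lowercase
        self._frames: dict[str, "DataBlock"] = {}

    @property
    def categories(self) -> dict[str, Category]:
        """Ordered mapping original category name -> Category."""
        return {c.name: c for c in self._categories.values()}

    @property
    def save_frames(self) -> dict[str, "DataBlock"]:
        return dict(self._frames)

    def __iter__(self) -> Iterator[Category]:
        return iter(self._categories.values())

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._categories

    def get_category(self, name: str) -> Category | None:
        """Case-insensitive category lookup; None on a miss, never raises."""
        return self._categories.get(name.lower())

    def __getitem__(self, name: str) -> Category:
        cat = self.get_category(name)
        if cat is None:
            raise CifKeyError(
                f"block {self.id!r} has no category {name!r}"
            )
        return cat

    def add_category(self, category: Category) -> None:
        key = category.name.lower()
        if key in self._categories:
            raise ValueError(
                f"duplicate category {category.name!r} in block {self.id!r}"
            )
        self._categories[key] = category

    def set_item(
        self, category_name: str, keyword: str, values: list[str]
    ) -> Category:
        """Create or update a column; creates the category when absent
        (loop form iff more than one value)."""
        values = [str(v) for v in values]
        if not values:
            raise CifShapeError(
                f"cannot set {category_name}.{keyword} to an empty column"
            )
        cat = self.get_category(category_name)
        if cat is None:
            cat = Category(
                category_name, {keyword: values}, is_loop=len(values) > 1
            )
            self._categories[category_name.lower()] = cat
        else:
            cat.set_column(keyword, values)
        return cat

    def remove_category(self, name: str) -> bool:
        """Remove a category (case-insensitive); returns False when it was
        not present (a no-op)."""
        return self._categories.pop(name.lower(), None) is not None

    def add_save_frame(self, frame: "DataBlock") -> None:
        self._frames[frame.id] = frame

    def search(
        self,
        category_name: str,
        keyword: str,
        pattern: str,
        as_regex: bool = False,
    ) -> list[tuple[int, dict[str, str]]]:
        return self[category_name].search(keyword, pattern, as_regex)

    def __repr__(self) -> str:
        return (
            f"<DataBlock {self.id!r}: {len(self._categories)} categories, "
            f"{len(self._frames)} save frames>"
        )


class CifFile:
    """Ordered collection of named data blocks; the top-level document."""

    def __init__(self, source_name: str | None = None):
        self.source_name = source_name
        self._blocks: dict[str, DataBlock] = {}

    @property
    def blocks(self) -> dict[str, DataBlock]:
        return dict(self._blocks)

    @property
    def block_ids(self) -> list[str]:
        return list(self._blocks)

    def __len__(self) -> int:
        return len(self._blocks)

    def __iter__(self) -> Iterator[DataBlock]:
        return iter(self._blocks.values())

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._blocks

    def __getitem__(self, block_id: str) -> DataBlock:
        try:
            return self._blocks[block_id]
        except KeyError:
            raise CifKeyError(f"no data block {block_id!r}") from None

    def add_block(self, block: DataBlock) -> None:
        if block.id in self._blocks:
            raise ValueError(f"duplicate block id {block.id!r}")
        self._blocks[block.id] = block

    def new_block(self, block_id: str) -> DataBlock:
        block = DataBlock(block_id)
        self.add_block(block)
        return block

    def first_block(self) -> DataBlock:
        if not self._blocks:
            raise CifKeyError("document has no data blocks")
        return next(iter(self._blocks.values()))

    def __repr__(self) -> str:
        return f"<CifFile: blocks {self.block_ids!r}>"


# -- plain-mapping representation ------------------------------------------


def _category_to_plain(cat: Category) -> dict[str, object]:
    if cat.is_loop:
        return {kw: list(col) for kw, col in cat.columns.items()}
    return {kw: col[0] for kw, col in cat.columns.items()}


def to_plain_mapping(cif: CifFile) -> dict[str, dict[str, dict[str, object]]]:
    """Nested-dictionary form: block id -> category -> keyword -> value.

    Key-value items map to single strings, loop columns to lists of strings.
    Save frames appear under the reserved key ``"_save_frames"`` within
    their block (frame name -> category -> keyword -> value); ordinary entry
    files have none.
    """
    out: dict[str, dict[str, dict[str, object]]] = {}
    for block in cif:
        cats: dict[str, object] = {
            cat.name: _category_to_plain(cat) for cat in block
        }
        if block.save_frames:
            cats["_save_frames"] = {
                name: {
                    c.name: _category_to_plain(c) for c in frame
                }
                for name, frame in block.save_frames.items()
            }
        out[block.id] = cats
    return out


def _category_from_plain(name: str, items: Mapping[str, object]) -> Category:
    if not isinstance(items, Mapping) or not items:
        raise TypeError(
            f"category {name!r} must be a non-empty mapping of keywords"
        )
    kinds = {isinstance(v, (list, tuple)) for v in items.values()}
    if len(kinds) > 1:
        raise CifShapeError(
            f"category {name!r} mixes scalar and list values"
        )
    is_loop = kinds == {True}
    columns: dict[str, list[str]] = {}
    length = None
    for kw, v in items.items():
        if is_loop:
            col = list(v)
            if length is None:
                length = len(col)
            elif len(col) != length:
                raise CifShapeError(
                    f"ragged columns in category {name!r}: {kw!r} has "
                    f"{len(col)} values, expected {length}"
                )
        else:
            col = [v]
        for cell in col:
            if not isinstance(cell, str):
                raise TypeError(
                    f"value for {name}.{kw} must be a string, "
                    f"got {type(cell).__name__}"
                )
        columns[kw] = col
    return Category(name, columns, is_loop=is_loop)


def from_plain_mapping(mapping: Mapping[str, object]) -> CifFile:
    """Inverse of :func:`to_plain_mapping` (identity up to semantic
    equality).  Scalar leaves become key-value items, lists become loop
    columns; ragged lists raise a shape error, non-string leaves a
    TypeError."""
    if not isinstance(mapping, Mapping):
        raise TypeError("expected a mapping of block ids")
    cif = CifFile()
    for block_id, cats in mapping.items():
        if not isinstance(cats, Mapping):
            raise TypeError(f"block {block_id!r} must map category names")
        block = cif.new_block(str(block_id))
        for cat_name, items in cats.items():
            if cat_name == "_save_frames":
                for frame_name, frame_cats in items.items():
                    frame = DataBlock(str(frame_name))
                    for fc_name, fc_items in frame_cats.items():
                        frame.add_category(
                            _category_from_plain(fc_name, fc_items)
                        )
                    block.add_save_frame(frame)
                continue
            block.add_category(_category_from_plain(cat_name, items))
    return cif


# -- semantic equality ------------------------------------------------------


def _blocks_equal(a: DataBlock, b: DataBlock) -> bool:
    a_cats = list(a)
    b_cats = list(b)
    if {c.name.lower() for c in a_cats} != {c.name.lower() for c in b_cats}:
        return False
    for cat in a_cats:
        other = b.get_category(cat.name)
        if other is None or not cat.equals(other):
            return False
    a_frames = a.save_frames
    b_frames = b.save_frames
    if list(a_frames) != list(b_frames):
        return False
    return all(_blocks_equal(a_frames[n], b_frames[n]) for n in a_frames)


def semantically_equal(a: CifFile, b: CifFile) -> bool:
    """Equality on content: block ids in order, category name sets
    (case-insensitive), keyword lists and value lists.  Formatting, quoting
    style and the loop flag are excluded."""
    if a.block_ids != b.block_ids:
        return False
    return all(_blocks_equal(a[i], b[i]) for i in a.block_ids)
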