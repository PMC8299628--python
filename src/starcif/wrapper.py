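"""Attribute-style, searchable view over the plain-mapping representation.

``CifWrapper`` lets document content be reached with dot notation —
``doc.demo.exptl.method`` — and exposes the string/regex search helpers on
each category.  It is a *view*: it stores the nested plain mapping (or
derives it from a CifFile) and adds no storage of its own, so the three
representations always agree on content.

Names that are not valid Python identifiers, collide with a method of the
wrapper, or start with an underscore are reached through the subscript
escape accessor: ``doc["1cbs"]["atom_site"]["id"]``.
"""

from __future__ import annotations

from typing import Iterator, Mapping

from .errors import CifKeyError
from .model import match_indices

__all__ = ["CifWrapper", "BlockWrapper", "CategoryWrapper"]


class _View:
    """Shared case-insensitive mapping view machinery."""

    _kind = "item"

    def __init__(self, mapping: Mapping[str, object]):
        object.__setattr__(self, "_mapping", mapping)
        object.__setattr__(
            self, "_lower", {k.lower(): k for k in mapping}
        )

    def _get(self, name: str):
        key = self._lower.get(name.lower())
        if key is None:
            raise CifKeyError(
                f"no {self._kind} named {name!r} "
                f"(available: {', '.join(self._mapping)})"
            )
        return self._wrap(key, self._mapping[key])

    def _wrap(self, key: str, value):
        raise NotImplementedError

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self._get(name)
        except CifKeyError as exc:
            raise AttributeError(str(exc)) from None

    def __getitem__(self, name: str):
        return self._get(name)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._lower

    def __iter__(self) -> Iterator[str]:
        return iter(self._mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    def keys(self):
        return self._mapping.keys()

    def to_plain_mapping(self):
        return self._mapping

    def __dir__(self):
        return sorted(set(super().__dir__()) | set(self._mapping))


class CategoryWrapper(_View):
    """Dot access to keyword values plus row-oriented search.

    A keyword attribute yields a single string for a key-value item and a
    list of strings for a loop column, mirroring the plain mapping.
    """

    _kind = "keyword"

    def __init__(self, name: str, mapping: Mapping[str, object]):
        super().__init__(mapping)
        object.__setattr__(self, "name", name)

    def _wrap(self, key: str, value):
        return value

    def _column(self, keyword: str) -> list[str]:
        value = self._get(keyword)
        return value if isinstance(value, list) else [value]

    @property
    def row_count(self) -> int:
        first = next(iter(self._mapping.values()))
        return len(first) if isinstance(first, list) else 1

    def rows(self) -> Iterator[dict[str, str]]:
        columns = {k: self._column(k) for k in self._mapping}
        for r in range(self.row_count):
            yield {k: col[r] for k, col in columns.items()}

    def search(
        self, keyword: str, pattern: str, as_regex: bool = False
    ) -> list[tuple[int, dict[str, str]]]:
        """Rows whose ``keyword`` value matches ``pattern`` exactly, or by
        regex search when ``as_regex``; 0-based ascending indices."""
        hits = match_indices(self._column(keyword), pattern, as_regex)
        all_rows = list(self.rows())
        return [(i, all_rows[i]) for i in hits]

    def __repr__(self) -> str:
        return f"<CategoryWrapper {self.name!r}: keywords {list(self._mapping)!r}>"


class BlockWrapper(_View):
    """Dot access to the categories of one data block."""

    _kind = "category"

    def __init__(self, block_id: str, mapping: Mapping[str, object]):
        categories = {
            k: v for k, v in mapping.items() if k != "_save_frames"
        }
        super().__init__(categories)
        object.__setattr__(self, "id", block_id)
        object.__setattr__(
            self, "save_frames",
            {
                name: BlockWrapper(name, frame)
                for name, frame in mapping.get("_save_frames", {}).items()
            },
        )

    def _wrap(self, key: str, value):
        return CategoryWrapper(key, value)

    def search(
        self,
        category: str,
        keyword: str,
        pattern: str,
        as_regex: bool = False,
    ) -> list[tuple[int, dict[str, str]]]:
        return self._get(category).search(keyword, pattern, as_regex)

    def __repr__(self) -> str:
        return f"<BlockWrapper {self.id!r}: categories {list(self._mapping)!r}>"


class CifWrapper(_View):
    """Document-level wrapper; attributes (or subscripts) are block ids."""

    _kind = "data block"

    def __init__(self, source):
        # Accept either the plain mapping or anything exposing one.
        if hasattr(source, "blocks") and not isinstance(source, Mapping):
            from .model import to_plain_mapping

            source = to_plain_mapping(source)
        super().__init__(source)

    def _wrap(self, key: str, value):
        return BlockWrapper(key, value)

    def first_block(self) -> BlockWrapper:
        if not self._mapping:
            raise CifKeyError("document has no data blocks")
        key = next(iter(self._mapping))
        return BlockWrapper(key, self._mapping[key])

    def __repr__(self) -> str:
        return f"<CifWrapper: blocks {list(self._mapping)!r}>"
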