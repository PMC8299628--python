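"""Seeded generator of grammatically diverse synthetic CIF documents.

Each generated fixture carries its own ground truth: the document text, the
exact model a correct parser must produce, and the (block, category, row)
counts.  The text is rendered by the generator itself — with randomised
spacing, comments, blank lines and quoting choices — independently of the
package's writer, so round-trip and oracle tests are not circular.

Value classes mimic what the archive actually contains:

* BARE      — numbers and short identifiers (``1.458``, ``CA``, ``ALA``);
* SPACED    — phrases with internal spaces (``X-RAY DIFFRACTION`` style);
* QUOTED_MIX— values with embedded quote characters (names, free text);
* MULTILINE — multi-line text (sequences, software descriptions);
* NULLS     — the "." (inapplicable) and "?" (unknown) conventions.

Determinism: the same FixtureSpec always yields byte-identical text and an
equal model.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Iterable

from .model import Category, CifFile, DataBlock

__all__ = ["ValueClass", "FixtureSpec", "Fixture", "generate_fixture",
           "edge_case_corpus"]


class ValueClass(enum.Enum):
    BARE = "bare"
    SPACED = "spaced"
    QUOTED_MIX = "quoted_mix"
    MULTILINE = "multiline"
    NULLS = "nulls"


ALL_VALUE_CLASSES = frozenset(ValueClass)

_CATEGORY_POOL = [
    "atom_site", "entity", "exptl", "cell", "chem_comp", "chem_comp_bond",
    "struct", "citation", "entity_poly", "pdbx_struct_assembly",
    "refine", "symmetry", "database_2", "audit_author", "software",
]
_KEYWORD_POOL = [
    "id", "type_symbol", "label_atom_id", "name", "value", "method",
    "formula", "pdbx_description", "details", "occupancy", "number",
    "code", "title", "version", "comp_id",
]
_BARE_WORDS = [
    "1.458", "C", "N", "O", "CA", "ALA", "GLY", "HOH", "1", "2", "42",
    "-3.21", "0.997", "x12", "A", "B", "yes", "no", "1tqn", "P2(1)",
]
_PHRASE_WORDS = [
    "X-RAY", "DIFFRACTION", "ELECTRON", "MICROSCOPY", "SOLUTION", "NMR",
    "retinoic", "acid", "binding", "protein", "flagellar", "motor",
]
_QUOTEY = [
    "O'Brien", 'the "best" model', "it's fine", "5' end", 'said "stop"',
    "N-term' cap",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic document.

    ``loop_fraction`` is the probability that a category takes the tabular
    (loop) form; ``max_rows`` bounds loop length; ``value_alphabet`` selects
    which value classes may appear (each enabled class is guaranteed to
    appear at least once when the document has room for it).
    """

    n_blocks: int = 1
    categories_per_block: int = 3
    loop_fraction: float = 0.5
    max_rows: int = 5
    value_alphabet: frozenset[ValueClass] = ALL_VALUE_CLASSES
    include_save_frames: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.categories_per_block < 1:
            raise ValueError("need at least one block and one category")
        if not 0.0 <= self.loop_fraction <= 1.0:
            raise ValueError("loop_fraction must be within [0, 1]")
        if self.max_rows < 1:
            raise ValueError("max_rows must be positive")
        if not self.value_alphabet:
            raise ValueError("value_alphabet must enable at least one class")
        object.__setattr__(
            self, "value_alphabet", frozenset(self.value_alphabet)
        )


@dataclass
class Fixture:
    """A generated document plus its ground truth."""

    text: str
    model: CifFile
    n_blocks: int
    n_categories: int
    n_rows: int

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_blocks, self.n_categories, self.n_rows)


def _value(rng: random.Random, cls: ValueClass) -> str:
    if cls == ValueClass.BARE:
        return rng.choice(_BARE_WORDS)
    if cls == ValueClass.SPACED:
        return " ".join(
            rng.choice(_PHRASE_WORDS) for _ in range(rng.randint(2, 4))
        )
    if cls == ValueClass.QUOTED_MIX:
        return rng.choice(_QUOTEY)
    if cls == ValueClass.MULTILINE:
        lines = [
            " ".join(rng.choice(_PHRASE_WORDS) for _ in range(rng.randint(1, 3)))
            for _ in range(rng.randint(2, 4))
        ]
        if rng.random() < 0.3:
            lines.insert(1, "")  # blank interior line
        return "\n".join(lines)
    return rng.choice([".", "?"])


def _needs_quote(v: str) -> bool:
    from .writer import _bare_ok

    return not _bare_ok(v)


def _render_value(rng: random.Random, v: str) -> str:
    """A valid serialization of v, chosen with some randomness so the corpus
    exercises all quoting styles (intentionally not the package writer)."""
    if "\n" in v:
        return "\n;" + v + "\n;\n"
    sq_ok = all(
        not (ch == "'" and (i + 1 < len(v) and v[i + 1] in " \t"))
        for i, ch in enumerate(v)
    )
    dq_ok = all(
        not (ch == '"' and (i + 1 < len(v) and v[i + 1] in " \t"))
        for i, ch in enumerate(v)
    )
    forms = []
    if not _needs_quote(v):
        forms.append(v)
    if sq_ok:
        forms.append(f"'{v}'")
    if dq_ok:
        forms.append(f'"{v}"')
    if not forms:
        return "\n;" + v + "\n;\n"
    weights = [3] + [1] * (len(forms) - 1)  # prefer the plain form
    return rng.choices(forms, weights=weights, k=1)[0]


def _maybe_comment(rng: random.Random, out: list[str]) -> None:
    roll = rng.random()
    if roll < 0.15:
        out.append(f"# {rng.choice(_PHRASE_WORDS).lower()} comment\n")
    elif roll < 0.25:
        out.append("\n")


def _pick_names(rng: random.Random, pool: list[str], n: int) -> list[str]:
    names = rng.sample(pool, min(n, len(pool)))
    i = 0
    while len(names) < n:
        names.append(f"{rng.choice(pool)}_{i}")
        i += 1
    return names


class _BlockBuilder:
    def __init__(self, rng: random.Random, spec: FixtureSpec):
        self.rng = rng
        self.spec = spec
        # Cycle through enabled classes so each appears as soon as there is
        # room, then draw freely.
        self._pending = sorted(spec.value_alphabet, key=lambda c: c.value)

    def next_value(self) -> str:
        rng = self.rng
        if self._pending:
            cls = self._pending.pop(0)
        else:
            cls = rng.choice(sorted(self.spec.value_alphabet,
                                    key=lambda c: c.value))
        return _value(rng, cls)

    def build_category(self, name: str) -> Category:
        rng = self.rng
        n_kw = rng.randint(1, 4)
        keywords = _pick_names(rng, _KEYWORD_POOL, n_kw)
        is_loop = rng.random() < self.spec.loop_fraction
        rows = rng.randint(1, self.spec.max_rows) if is_loop else 1
        columns = {
            kw: [self.next_value() for _ in range(rows)] for kw in keywords
        }
        return Category(name, columns, is_loop=is_loop)


def _render_category(rng: random.Random, cat: Category, out: list[str]) -> None:
    _maybe_comment(rng, out)
    if cat.is_loop:
        out.append("loop_\n")
        for kw in cat.keywords:
            out.append(f"_{cat.name}.{kw}\n")
        # Values in row-major order with random line grouping: whitespace
        # between loop values is free-form.
        flat = [v for row in cat.rows() for v in row.values()]
        line: list[str] = []
        for v in flat:
            rendered = _render_value(rng, v)
            if rendered.startswith("\n;"):
                if line:
                    out.append(" ".join(line) + "\n")
                    line = []
                out.append(rendered[1:])
            else:
                line.append(rendered)
                if rng.random() < 0.4:
                    out.append((" " * rng.randint(1, 3)).join(line) + "\n")
                    line = []
        if line:
            out.append(" ".join(line) + "\n")
    else:
        for kw in cat.keywords:
            rendered = _render_value(rng, cat[kw][0])
            sep = " " * rng.randint(1, 4)
            if rendered.startswith("\n;"):
                out.append(f"_{cat.name}.{kw}{rendered}")
            elif rng.random() < 0.1:
                out.append(f"_{cat.name}.{kw}\n{rendered}\n")
            else:
                out.append(f"_{cat.name}.{kw}{sep}{rendered}\n")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one document with its expected model and counts."""
    rng = random.Random(spec.seed)
    model = CifFile()
    out: list[str] = []
    n_categories = 0
    n_rows = 0

    block_ids = [
        f"fix{spec.seed % 10_000}_{b}" for b in range(spec.n_blocks)
    ]
    for block_id in block_ids:
        block = model.new_block(block_id)
        out.append(f"data_{block_id}\n")
        builder = _BlockBuilder(rng, spec)
        names = _pick_names(rng, _CATEGORY_POOL, spec.categories_per_block)
        for name in names:
            cat = builder.build_category(name)
            block.add_category(cat)
            n_categories += 1
            n_rows += cat.row_count
            _render_category(rng, cat, out)
        if spec.include_save_frames:
            for f in range(rng.randint(1, 2)):
                frame = DataBlock(f"frame_{block_id}_{f}")
                out.append(f"save_{frame.id}\n")
                frame_names = _pick_names(rng, _CATEGORY_POOL, 2)
                for name in frame_names:
                    cat = builder.build_category(name)
                    frame.add_category(cat)
                    n_categories += 1
                    n_rows += cat.row_count
                    _render_category(rng, cat, out)
                out.append("save_\n")
                block.add_save_frame(frame)
        _maybe_comment(rng, out)
    return Fixture(
        text="".join(out),
        model=model,
        n_blocks=spec.n_blocks,
        n_categories=n_categories,
        n_rows=n_rows,
    )


def random_specs(n: int, seed: int) -> list[FixtureSpec]:
    """A reproducible family of n diverse specs (for corpus-wide tests)."""
    rng = random.Random(seed)
    alphabets = [
        ALL_VALUE_CLASSES,
        frozenset({ValueClass.BARE}),
        frozenset({ValueClass.BARE, ValueClass.SPACED}),
        frozenset({ValueClass.QUOTED_MIX, ValueClass.NULLS}),
        frozenset({ValueClass.MULTILINE, ValueClass.BARE}),
    ]
    specs = []
    for i in range(n):
        specs.append(
            FixtureSpec(
                n_blocks=rng.randint(1, 3),
                categories_per_block=rng.randint(1, 5),
                loop_fraction=rng.choice([0.0, 0.3, 0.5, 0.8, 1.0]),
                max_rows=rng.randint(1, 8),
                value_alphabet=rng.choice(alphabets),
                include_save_frames=rng.random() < 0.3,
                seed=rng.randrange(2**31),
            )
        )
    return specs


def large_atom_site_document(
    n_rows: int, seed: int = 0, extra_categories: int = 3
) -> str:
    """A coordinate-heavy entry-style document with an ``atom_site`` loop of
    ``n_rows`` rows, for streaming/benchmark exercises.  Rendered directly
    for speed; still fully deterministic."""
    rng = random.Random(seed)
    parts = [f"data_big{seed}\n"]
    for i in range(extra_categories):
        parts.append(f"_meta_{i}.name 'generated entry {i}'\n")
    parts.append("loop_\n")
    for kw in ("group_PDB", "id", "type_symbol", "label_atom_id",
               "Cartn_x", "Cartn_y", "Cartn_z", "occupancy"):
        parts.append(f"_atom_site.{kw}\n")
    symbols = ["C", "N", "O", "S"]
    atoms = ["CA", "CB", "N", "O", "SG"]
    for i in range(1, n_rows + 1):
        x = rng.uniform(-50, 50)
        y = rng.uniform(-50, 50)
        z = rng.uniform(-50, 50)
        parts.append(
            f"ATOM {i} {rng.choice(symbols)} {rng.choice(atoms)} "
            f"{x:.3f} {y:.3f} {z:.3f} 1.00\n"
        )
    return "".join(parts)


def edge_case_corpus() -> list[tuple[str, str]]:
    """Named hand-written documents covering the tokenizer's edge cases:
    quotes inside words, comment-only files, empty block names, text fields
    with blank lines, null values, save frames, CRLF endings, plain-CIF
    tags, and more.  Used for oracle-agreement testing."""
    docs: list[tuple[str, str]] = [
        ("minimal", "data_x\n_a.b 1\n"),
        ("empty", ""),
        ("comment_only", "# just a comment\n# and another\n"),
        ("empty_block_name", "data_\n_a.b 1\n"),
        ("no_final_newline", "data_x\n_a.b 1"),
        ("crlf", "data_x\r\n_a.b 1\r\n"),
        ("tabs", "data_x\n_a.b\t'v 1'\n"),
        ("single_quotes", "data_x\n_exptl.method 'X-RAY DIFFRACTION'\n"),
        ("double_quotes", 'data_x\n_a.b "two words"\n'),
        ("quote_in_word", "data_x\n_a.b O'Brien\n"),
        ("quote_in_quotes", "data_x\n_a.b 'O'Brien'\n"),
        ("dquote_in_squotes", "data_x\n_a.b 'say \"hi\" now'\n"),
        ("trailing_quote", "data_x\n_a.b 'ends with ''\n"),
        ("hash_in_word", "data_x\n_a.b val#notcomment\n"),
        ("comment_after_value", "data_x\n_a.b 1 # trailing comment\n"),
        ("textfield", "data_x\n_a.b\n;line one\nline two\n;\n"),
        ("textfield_blank_lines", "data_x\n_a.b\n;first\n\nthird\n;\n"),
        ("textfield_semicolon_inline", "data_x\n_a.b\n;a ; b ; c\n;\n"),
        ("textfield_empty", "data_x\n_a.b\n;\n;\n"),
        ("textfield_hash", "data_x\n_a.b\n;# not a comment\n;\n"),
        ("nulls", "data_x\n_a.b .\n_a.c ?\n"),
        ("quoted_null", "data_x\n_a.b '.'\n"),
        ("loop_simple", "data_x\nloop_\n_a.i\n_a.s\n1 C\n2 N\n3 C\n"),
        ("loop_one_tag", "data_x\nloop_\n_a.i\n1\n2\n3\n4\n"),
        ("loop_values_packed", "data_x\nloop_\n_a.i\n_a.s\n1 C 2 N 3 C\n"),
        ("loop_textfield", "data_x\nloop_\n_a.i\n_a.t\n1\n;multi\nline\n;\n2 short\n"),
        ("two_blocks", "data_one\n_a.b 1\ndata_two\n_a.b 2\n"),
        ("case_data", "DATA_UPPER\n_a.b 1\n"),
        ("case_loop", "data_x\nLOOP_\n_a.i\n1\n"),
        ("save_frame", "data_d\nsave_ALA\n_chem_comp.id ALA\nsave_\n"),
        ("save_frame_case", "data_d\nSAVE_ala\n_chem_comp.id ALA\nSAVE_\n"),
        ("plain_cif_tag", "data_x\n_cell_length_a 5.19\n"),
        ("underscore_only_category", "data_x\n_mytag value\n"),
        ("value_on_next_line", "data_x\n_a.b\nvalue\n"),
        ("many_spaces", "data_x\n_a.b     1\n\n\n_a.c  2\n"),
        ("blank_lines_between", "data_x\n\n\n_a.b 1\n\n_c.d 2\n"),
        ("dollar_in_value", "data_x\n_a.b 'has $dollar'\n"),
        ("brackets_bare", "data_x\n_a.b x[1]\n"),
        ("numeric_variety", "data_x\nloop_\n_a.v\n1 -2.5 1e-4 .5 ?\n"),
        ("mixed_quotes_loop",
         "data_x\nloop_\n_a.v\n'one two' \"three four\" bare\n"),
        ("long_line",
         "data_x\n_a.b " + "x" * 300 + "\n"),
        ("empty_quoted", "data_x\n_a.b ''\n"),
        ("comment_between_loop_values",
         "data_x\nloop_\n_a.i\n1\n# interlude\n2\n"),
        ("semicolon_mid_line", "data_x\n_a.b v;w\n"),
        ("leading_whitespace_semicolon",
         "data_x\n_a.b\n ;not a textfield'\n"),
        ("heading_like_value", "data_x\n_a.b 'data_fake'\n"),
        ("loop_like_value", "data_x\n_a.b 'loop_'\n"),
        ("save_like_value", "data_x\n_a.b 'save_thing'\n"),
        ("tag_case_mixed", "data_x\n_Exptl.Method 'NMR'\n"),
        ("multi_category", "data_x\n_cell.a 1\n_cell.b 2\n_exptl.m 'E M'\n"),
    ]
    return docs
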