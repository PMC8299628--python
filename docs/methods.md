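# Methods

## Scope and model

starcif implements CIF 1.1 syntax as used by PDBx/mmCIF archive files,
small-molecule CIF and the wwPDB Chemical Component Dictionary: data
blocks, key-value and loop categories, save frames, both quoting styles,
semicolon text fields and comments. It is deliberately a *syntactic*
layer: values are kept verbatim as strings (including the `.`/`?` null
conventions), with no numeric coercion, no dictionary (DDL) validation of
types, controlled vocabularies or ranges, and no interpretation of
coordinates. CIF2 constructs (triple-quoted strings, lists, tables) and
the full STAR features CIF does not use (nested loops, `stop_`,
`global_`) are out of scope; the two reserved STAR words are rejected with
an explicit error rather than silently read as values, since their
presence almost always indicates a corrupt or mis-typed file.

## Tokenizer

The scanner is a single character-level pass with three context rules:

* a quote closes a quoted string only when followed by whitespace or end
  of line (CIF 1.1), so interior apostrophes (`'O'Brien rule'`) survive;
* `;` opens a text field only as the first character of a line; the field
  ends at the next line whose first character is `;`, and the value is the
  enclosed lines joined with `\n` (no trailing newline);
* `#` starts a comment only where a new lexeme could start; embedded in a
  bare word it is content.

Reserved words and headings match case-insensitively while token text
preserves source case, enabling faithful rewriting. CRLF is normalised to
LF before scanning. A bare `data_` (empty block id) is accepted with a
warning because such files occur in the wild. Line length is not enforced
on read — archive files legitimately reach 2048 columns — only on write.
Lexical errors (unterminated quote or text field, non-ASCII byte under
`strict_ascii`) carry the 1-based line of the offending construct.

## Grammar and merging

Tags split at the **first** period; period-less plain-CIF tags (e.g.
`_cell_length_a`) become a synthetic one-keyword category named after the
whole tag, with the implicit keyword spelled identically to the category
name and an `is_plain` flag so the writer restores the original `_tag
value` spelling.

Degenerate inputs are resolved explicitly rather than silently:

* duplicate block ids: the later block is renamed with a numeric suffix
  (`x` → `x_2`) and a warning recorded — lossless over last-wins;
* a category restated within a block: identical keyword lists (loop form)
  append rows (split loops occur in hand-edited files); disjoint keywords
  with matching row counts merge as columns (this is also the ordinary
  accumulation of key-value items); anything else is a shape error;
* a duplicate key-value item: last value wins, with a warning;
* a loop with tags but no values: an error — the model invariant requires
  at least one row, and silently dropping an empty loop would hide
  truncation;
* a loop whose value count is not a multiple of its tag count, mixed
  categories within one loop's tags, a dangling tag, a value before any
  tag, or an unterminated save frame: errors naming the construct and its
  line.

Category filters apply uniformly to block and save-frame interiors.
Filtered-out values are counted in the diagnostics (`discarded_values`)
and discarded as they stream past; the parser accepts a token *generator*,
so a filtered parse never holds the skipped columns. The acceptance suite
verifies this with a memory-peak measurement on a 2.4-million-value
document.

## Writer

Quoting is minimal and ordered bare → single-quoted → double-quoted →
semicolon text field, with the guarantee (property-tested over random
printable strings) that re-tokenizing any emitted fragment yields exactly
one value token equal to the original string. `.` and `?` are written
bare, as their conventional meaning requires. The only unrepresentable
CIF 1.1 value — a multi-line string with a line beginning with `;` — raises
a dedicated representation error naming the item.

Formatting choices are cosmetic and fixed: `#` separator lines in archive
style, key-value tags padded to a common width per category, loop columns
padded to the widest cell (`align_loop_columns`), rows wrapped only at
value boundaries when exceeding `max_line_length` (default 2048, minimum
80; lines inside text fields may exceed it when reproducing long source
lines). An inline value that alone exceeds the limit is demoted to a text
field when one is representable. Categories are emitted in model order;
block categories precede save frames because the model stores the two in
separate ordered maps (the layout used by the CCD). Because the output is
a pure function of model content, write ∘ parse ∘ write is byte-stable,
which the round-trip suite asserts for every fixture.

## The three representations

The plain mapping is the contract: block id → category → keyword → value,
scalars for key-value items and lists for loop columns, JSON-serializable
by construction (save frames appear under a reserved `_save_frames` key).
The attribute wrapper is a *view* over that mapping — it adds dot access
and row search but no storage, so the representations cannot drift apart;
subscript access is the escape hatch for names that collide with wrapper
methods or are not Python identifiers. Converting mapping → model treats
any list-valued category as a loop; since semantic equality (same block
ids in order, same category name sets case-insensitively, same keyword
lists, same value lists) deliberately excludes the loop flag and
formatting, the conversion is an identity under that equivalence. A
category mixing scalar and list leaves is rejected as malformed.

## Synthetic-document generator

Fixtures are the package's test substrate; each carries its own ground
truth (text, expected model, expected counts), with the text rendered by
the generator itself — randomised spacing, comments, blank lines, value
layout and quoting choices — independently of the package writer, so
round-trip and oracle tests are not circular. Value classes mirror what
the archive contains: bare numerics/identifiers, spaced phrases, values
with embedded quotes, multi-line text, and the null conventions; each
enabled class is injected at least once per document when there is room.
Default spec: 1 block, 3 categories, loop probability 0.5, up to 5 rows —
small enough that corpus-scale suites (hundreds of fixtures) run in
seconds, diverse enough to hit every token kind. The corpus-scale
problem sizes used by the tests and the acceptance script (200 round-trip
fixtures, ≥50 oracle documents, 50 filter subsets, a 300,000-row
coordinate table mirroring a large flagellar-machine entry) were chosen to
exercise every value class and the streaming path at realistic archive
scale.

What generated fixtures do **not** emulate: real mmCIF category
vocabularies and inter-category consistency, dictionary conformance,
megabyte-scale annotation sections, and non-ASCII contamination. Passing
the synthetic suites therefore demonstrates syntactic correctness and
round-trip fidelity, not semantic validity of any particular archive
entry; the optional archival check (PDB entry 1tqn, 3999 `atom_site`
rows) covers one real updated entry when a cached copy or network access
is available.

## Numerical and interface conventions

Row indices in the search API are 0-based; file line numbers in tokens,
warnings and errors are 1-based. Warnings go to the logging system and to
`ParseDiagnostics.warnings`; the CLI routes them to standard error, data
to standard output. Benchmarks (`cif bench`, default 7 repeats) report
per-run and mean wall-clock times but are never asserted against absolute
thresholds — timing is hardware-dependent; the only timing-adjacent
assertion in the suite is the memory bound on the streaming ignore-parse.

## Known limitations

* No CIF2, binary mmCIF, or STAR nested loops.
* No dictionary-driven validation or parent-child relational checks.
* The original interleaving of categories and save frames within a block
  is not preserved (frames are written after categories).
* A quoted `.` or `?` is indistinguishable from the bare null after
  parsing, since quoting is resolved at the lexical layer.
* Reading loads the whole document text into memory; streaming applies to
  the token-to-model stage, not to file I/O.
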