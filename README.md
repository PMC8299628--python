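# starcif

A dependency-light Python library (plus a thin `cif` command-line tool) for
reading, searching, editing and writing STAR/CIF/PDBx-mmCIF files — the
master text format of the Protein Data Bank archive and of the wwPDB
Chemical Component Dictionary.

## Who this is for

Structural bioinformaticians and tool authors who need programmatic access
to mmCIF content — entry annotations, coordinate tables, CCD save frames —
without pulling in a structure-interpretation stack. starcif is a purely
syntactic parser: it never interprets coordinates or applies dictionary
(DDL) validation, which is precisely what keeps it fast and predictable.

## The format and the model

A CIF document is one or more **data blocks** (`data_<id>`), each holding
**data items**. An item tag `_category.keyword` names a column; categories
come in two shapes:

* **key-value** — one row, written as inline `_cat.key value` lines;
* **tabular (loop)** — introduced by `loop_`, with k tag columns followed by
  row-major values (n values ⇒ n/k rows).

Values are strings; `.` means *inapplicable* and `?` means *unknown*.
Multi-line values use semicolon text fields; dictionaries and the CCD nest
`save_`-delimited frames inside blocks. starcif exposes a parsed document
in three interchangeable representations:

1. a **plain nested mapping** `block id → category → keyword → value`
   (a scalar for key-value items, a list for loop columns; JSON-ready),
2. a **searchable attribute-style wrapper** (`doc.demo.exptl.method`) with
   exact and regex row search,
3. a **mutable model** (`CifFile → DataBlock → Category`) supporting
   adding/removing categories and items.

The writer accepts any of the three and emits text with minimal correct
quoting (bare → single-quoted → double-quoted → text field); its output
re-parses to a semantically equal model and a second rewrite is
byte-identical. While parsing, category filters (`only=…` / `ignore=…`)
skip unwanted categories without ever storing their values — ignoring
`atom_site` makes annotation-only reads of coordinate-heavy entries cheap.

## Worked example

```python
import starcif

DOC = """\
data_demo
_exptl.method 'X-RAY DIFFRACTION'
loop_
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
1 C CA
2 N N
3 C CB
"""

plain   = starcif.read_text(DOC, starcif.Representation.PLAIN)
wrapped = starcif.read_text(DOC, starcif.Representation.WRAPPED)
model   = starcif.read_text(DOC, starcif.Representation.MODEL)

print(plain["demo"]["exptl"])                       # {'method': 'X-RAY DIFFRACTION'}
print(wrapped.demo.exptl.method)                    # X-RAY DIFFRACTION
print(model["demo"]["atom_site"].item_values("id")) # ['1', '2', '3']

hits = wrapped.demo.atom_site.search("type_symbol", "C")
print([i for i, _ in hits])                         # [0, 2]  (0-based row indices)
```

The two carbon atoms sit in rows 0 and 2 of the three-row `atom_site` loop;
the same content is visible through all three representations, and
`starcif.write(model)` serializes any of them back to valid CIF. More
narrative scripts live in `examples/`.

## Command line

```sh
cif convert entry.cif                 # plain-mapping JSON on stdout
cif convert entry.cif --format cif -o normalized.cif
cif extract entry.cif atom_site --keywords id,type_symbol   # TSV table
cif check entry.cif                   # syntax check, counts + warnings
cif bench entry.cif --repeats 7 --ignore atom_site          # timed parses
```

Gzip-compressed input/output is handled by the `.gz` extension. `--only`
and `--ignore` take comma-separated category lists.

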