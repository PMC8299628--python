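"""Read one document in all three representations and search a column.

The same content is exposed as a plain nested dictionary, an
attribute-style wrapper and the mutable model; the search returns the
0-based indices of the matching rows together with the full rows.
"""

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

plain = starcif.read_text(DOC, starcif.Representation.PLAIN)
wrapped = starcif.read_text(DOC, starcif.Representation.WRAPPED)
model = starcif.read_text(DOC, starcif.Representation.MODEL)

print("plain mapping:", plain["demo"]["exptl"])
print("wrapped dot access:", wrapped.demo.exptl.method)
print("model column:", model["demo"]["atom_site"].item_values("id"))

hits = wrapped.demo.atom_site.search("type_symbol", "C")
print("exact search for carbon: rows", [i for i, _ in hits])

regex_hits = model["demo"].search("atom_site", "label_atom_id", "^C", as_regex=True)
print("regex ^C on atom names:", [(i, row["label_atom_id"]) for i, row in regex_hits])

# The three representations always agree on content.
assert wrapped.to_plain_mapping() == plain
assert starcif.to_plain_mapping(model) == plain
print("all three representations agree")
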