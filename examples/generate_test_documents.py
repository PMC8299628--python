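"""Generate seeded synthetic documents with known ground truth.

Each fixture carries the exact model a correct parser must produce, so the
generator doubles as a self-checking test oracle: parsing the text must
reproduce the expected model, block for block and value for value.
"""

import starcif
from starcif import FixtureSpec, ValueClass

spec = FixtureSpec(
    n_blocks=2,
    categories_per_block=3,
    loop_fraction=0.5,
    max_rows=4,
    value_alphabet=frozenset(
        {ValueClass.BARE, ValueClass.SPACED, ValueClass.MULTILINE}
    ),
    include_save_frames=False,
    seed=42,
)
fx = starcif.generate_fixture(spec)

print(fx.text)
print(
    f"expected: {fx.n_blocks} blocks, {fx.n_categories} categories, "
    f"{fx.n_rows} rows"
)

parsed, diag = starcif.parse(starcif.tokenize(fx.text))
assert starcif.semantically_equal(parsed, fx.model)
assert (diag.block_count, diag.category_count, diag.row_total) == fx.counts
print("parsed model matches the generator's ground truth")
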