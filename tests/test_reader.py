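"""Grammar layer: parsing, filtering, diagnostics, error locality."""

from __future__ import annotations

import gzip
import random

import pytest

from starcif import (
    ALL_CATEGORIES,
    CategoryFilter,
    CifFileReader,
    CifShapeError,
    CifSyntaxError,
    FilterMode,
    Representation,
    from_plain_mapping,
    generate_fixture,
    parse,
    read,
    read_file,
    read_text,
    semantically_equal,
    to_plain_mapping,
    tokenize,
)
from starcif.fixtures import random_specs


class TestGrammar:
    def test_minimal_key_value_item(self):
        cif = read_text("data_x\n_a.b 1\n")
        assert cif.block_ids == ["x"]
        cat = cif["x"]["a"]
        assert cat.item_values("b") == ["1"]
        assert not cat.is_loop

    def test_tag_splits_at_first_period(self):
        cif = read_text("data_x\n_refine.pdbx_method_to_determine_struct MAD\n")
        cat = cif["x"]["refine"]
        assert cat.keywords == ["pdbx_method_to_determine_struct"]

    def test_periodless_tag_becomes_synthetic_category(self):
        cif = read_text("data_x\n_cell_length_a 5.19\n")
        cat = cif["x"]["cell_length_a"]
        assert cat.is_plain
        assert cat.item_values("cell_length_a") == ["5.19"]

    def test_loop_rows_from_value_count(self):
        cif = read_text("data_x\nloop_\n_s.a\n_s.b\n1 2 3 4 5 6\n")
        cat = cif["x"]["s"]
        assert cat.is_loop
        assert cat.row_count == 3
        assert cat.item_values("a") == ["1", "3", "5"]
        assert cat.item_values("b") == ["2", "4", "6"]

    def test_key_value_items_accumulate_into_one_category(self):
        cif = read_text("data_x\n_cell.a 1\n_cell.b 2\n_cell.c 3\n")
        assert cif["x"]["cell"].keywords == ["a", "b", "c"]

    def test_save_frames_parse_with_same_grammar(self):
        text = (
            "data_ccd\nsave_ALA\n_chem_comp.id ALA\n"
            "loop_\n_chem_comp_bond.atom_id_1\n_chem_comp_bond.atom_id_2\n"
            "N CA\nCA C\nsave_\n"
        )
        cif = read_text(text)
        frame = cif["ccd"].save_frames["ALA"]
        assert frame["chem_comp"].item_values("id") == ["ALA"]
        assert frame["chem_comp_bond"].row_count == 2
        assert cif["ccd"].categories == {}

    def test_multiple_blocks_keep_order(self):
        cif = read_text("data_b\n_a.x 1\ndata_a\n_a.x 2\n")
        assert cif.block_ids == ["b", "a"]

    def test_determinism(self):
        spec_text = generate_fixture(random_specs(1, seed=5)[0]).text
        one = to_plain_mapping(read_text(spec_text))
        two = to_plain_mapping(read_text(spec_text))
        assert one == two

    def test_parse_accepts_a_token_generator(self):
        toks = iter(tokenize("data_x\n_a.b 1\n"))
        cif, _ = parse(toks)
        assert cif["x"]["a"].item_values("b") == ["1"]


class TestWarningsAndMerging:
    def test_duplicate_block_ids_renamed_with_warning(self):
        cif, diag = parse(tokenize("data_x\n_a.b 1\ndata_x\n_a.b 2\n"))
        assert cif.block_ids == ["x", "x_2"]
        assert any("duplicate block" in msg for _, msg in diag.warnings)

    def test_empty_block_id_accepted_with_warning(self):
        cif, diag = parse(tokenize("data_\n_a.b 1\n"))
        assert cif.block_ids == [""]
        assert any("empty id" in msg for _, msg in diag.warnings)

    def test_split_loop_rows_appended(self):
        text = (
            "data_x\nloop_\n_s.a\n_s.b\n1 2\n"
            "loop_\n_s.a\n_s.b\n3 4\n"
        )
        cif, diag = parse(tokenize(text))
        assert cif["x"]["s"].item_values("a") == ["1", "3"]
        assert any("restated" in msg for _, msg in diag.warnings)

    def test_incompatible_restatement_is_shape_error(self):
        text = (
            "data_x\nloop_\n_s.a\n1 2 3\n"
            "loop_\n_s.b\n9\n"
        )
        with pytest.raises(CifShapeError, match="restated"):
            parse(tokenize(text))

    def test_duplicate_item_last_value_wins_with_warning(self):
        cif, diag = parse(tokenize("data_x\n_a.b 1\n_a.b 2\n"))
        assert cif["x"]["a"].item_values("b") == ["2"]
        assert any("duplicate item" in msg for _, msg in diag.warnings)

    def test_diagnostics_counts_match_generator(self, fixture_family):
        for fx in fixture_family:
            _, diag = parse(tokenize(fx.text))
            assert diag.block_count == fx.n_blocks
            assert diag.category_count == fx.n_categories
            assert diag.row_total == fx.n_rows


class TestErrors:
    @pytest.mark.parametrize(
        "text, exc, match",
        [
            ("data_x\n_a.b\n", CifSyntaxError, "no value"),
            ("data_x\n_a.b\nloop_\n", CifSyntaxError, "no value"),
            ("_a.b 1\n", CifSyntaxError, "outside any data block"),
            ("data_x\norphan\n", CifSyntaxError, "before any tag"),
            ("data_x\nloop_\n_s.a\n_s.b\n1 2 3 4 5\n", CifShapeError, "5 values"),
            ("data_x\nloop_\n_s.a\n_t.b\n1 2\n", CifSyntaxError, "mixes"),
            ("data_x\nloop_\n_s.a\n", CifSyntaxError, "no values"),
            ("data_x\nloop_\nnope\n", CifSyntaxError, "no tags"),
            ("data_x\nsave_f\n_a.b 1\n", CifSyntaxError, "not terminated"),
            ("data_x\nsave_f\nsave_g\n", CifSyntaxError, "nested"),
            ("data_x\nsave_\n", CifSyntaxError, "without an open"),
            ("data_x\nsave_f\n_a.b 1\ndata_y\n", CifSyntaxError, "not terminated"),
            ("save_f\n_a.b 1\nsave_\n", CifSyntaxError, "outside any data block"),
            ("loop_\n_a.b\n1\n", CifSyntaxError, "outside any data block"),
        ],
    )
    def test_syntax_errors_name_the_problem(self, text, exc, match):
        with pytest.raises(exc, match=match) as exc_info:
            parse(tokenize(text))
        assert exc_info.value.line is not None
        assert 1 <= exc_info.value.line <= text.count("\n") + 1


class TestFiltering:
    DOC = (
        "data_x\n_exptl.method NMR\n"
        "loop_\n_atom_site.id\n_atom_site.sym\n1 C\n2 N\n"
        "_cell.length_a 10\n"
    )

    def test_ignore_drops_category(self):
        cif = read_text(self.DOC, category_filter=CategoryFilter.ignore("atom_site"))
        assert cif["x"].get_category("atom_site") is None
        assert cif["x"].get_category("exptl") is not None

    def test_only_keeps_single_category(self):
        cif = read_text(self.DOC, category_filter=CategoryFilter.only("cell"))
        assert [c.name for c in cif["x"]] == ["cell"]

    def test_filter_names_case_insensitive(self):
        cif = read_text(self.DOC, category_filter=CategoryFilter.only("ATOM_SITE"))
        assert [c.name for c in cif["x"]] == ["atom_site"]

    def test_all_filter_rejects_names(self):
        with pytest.raises(ValueError):
            CategoryFilter(FilterMode.ALL, frozenset({"a"}))

    def test_filtered_values_counted_not_stored(self):
        _, diag = parse(
            tokenize(self.DOC), CategoryFilter.ignore("atom_site")
        )
        assert diag.discarded_values == 4
        assert diag.category_count == 2

    def test_filter_applies_inside_save_frames(self):
        text = "data_d\nsave_A\n_x.a 1\n_y.b 2\nsave_\n"
        cif = read_text(text, category_filter=CategoryFilter.ignore("y"))
        frame = cif["d"].save_frames["A"]
        assert frame.get_category("y") is None
        assert frame.get_category("x") is not None

    @staticmethod
    def _restrict(cif, keep):
        mapping = to_plain_mapping(cif)
        out = {}
        for block_id, cats in mapping.items():
            kept = {}
            for name, items in cats.items():
                if name == "_save_frames":
                    kept[name] = {
                        fn: {
                            cn: ci for cn, ci in fcats.items()
                            if cn.lower() in keep
                        }
                        for fn, fcats in items.items()
                    }
                elif name.lower() in keep:
                    kept[name] = items
            out[block_id] = kept
        return out

    def test_filter_equivalence_random_subsets(self, fixture_family, rng):
        """ONLY/IGNORE parses equal set-restrictions of the full parse."""
        for fx in rng.sample(fixture_family, 12):
            full = read_text(fx.text)
            names = {
                c.name.lower()
                for b in full
                for c in list(b) + [
                    c2 for f in b.save_frames.values() for c2 in f
                ]
            }
            subset = {n for n in names if rng.random() < 0.5}
            only = read_text(fx.text, category_filter=CategoryFilter(
                FilterMode.ONLY, frozenset(subset) or frozenset({"none"})))
            ignore = read_text(fx.text, category_filter=CategoryFilter(
                FilterMode.IGNORE, frozenset(subset) or frozenset({"none"})))
            keep_only = subset or {"none"}
            keep_ignore = {n for n in names if n not in keep_only}
            assert to_plain_mapping(only) == self._restrict(full, keep_only)
            assert to_plain_mapping(ignore) == self._restrict(full, keep_ignore)


class TestReadFrontEnd:
    def test_representations_agree(self):
        text = "data_x\n_a.b 1\nloop_\n_s.i\n1\n2\n"
        plain = read_text(text, Representation.PLAIN)
        wrapped = read_text(text, Representation.WRAPPED)
        model = read_text(text, Representation.MODEL)
        assert plain == {"x": {"a": {"b": "1"}, "s": {"i": ["1", "2"]}}}
        assert wrapped.to_plain_mapping() == plain
        assert to_plain_mapping(model) == plain

    def test_read_from_path_and_text(self, tmp_path):
        path = tmp_path / "t.cif"
        path.write_text("data_x\n_a.b 1\n")
        by_path = read(str(path))
        by_text = read("data_x\n_a.b 1\n")
        assert semantically_equal(by_path, by_text)
        assert by_path.source_name == str(path)

    def test_read_gzip_by_extension(self, tmp_path):
        path = tmp_path / "t.cif.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("data_x\n_a.b 1\n")
        cif = read_file(path)
        assert cif["x"]["a"].item_values("b") == ["1"]

    def test_read_file_object(self, tmp_path):
        path = tmp_path / "t.cif"
        path.write_text("data_x\n_a.b 1\n")
        with open(path) as fh:
            cif = read(fh)
        assert cif.block_ids == ["x"]

    def test_missing_file_raises_io_error(self):
        with pytest.raises(OSError):
            read_file("definitely_not_here.cif")

    def test_reader_facade(self):
        reader = CifFileReader(category_filter=CategoryFilter.only("a"))
        cif = reader.read("data_x\n_a.b 1\n_c.d 2\n")
        assert [c.name for c in cif["x"]] == ["a"]
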