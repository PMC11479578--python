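"""Tidy-table construction: column rules, joining conventions, writers."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbmlflat import (
    EntityRecord,
    SpeciesRef,
    as_tables,
    read_sbml,
    tabulate_entities,
    tabulate_reactions,
    write_tables,
)

from conftest import raw_counts


def _species(attrs, notes=None, annotation=None):
    return EntityRecord(
        component="species",
        attributes=attrs,
        notes=notes or [],
        annotation=annotation or {},
    )


class TestTabulateEntities:
    def test_no_notes_anywhere_no_notes_column(self):
        df = tabulate_entities([_species({"id": "a"}), _species({"id": "b"})])
        assert list(df.columns) == ["id"]

    def test_notes_joined_with_pipe(self):
        df = tabulate_entities([_species({"id": "a"}, notes=["a", "b"])])
        assert df.loc[0, "notes"] == "a|b"

    def test_annotation_joined_with_single_space(self):
        df = tabulate_entities(
            [_species({"id": "a"}, annotation={"hasPart": ["uri1", "uri2"]})]
        )
        assert df.loc[0, "annotation_hasPart"] == "uri1 uri2"

    def test_missing_distinct_from_empty_string(self):
        df = tabulate_entities(
            [_species({"id": "a", "name": ""}), _species({"id": "b"})]
        )
        assert df.loc[0, "name"] == ""
        assert pd.isna(df.loc[1, "name"])

    def test_column_order_attributes_notes_annotation(self):
        df = tabulate_entities(
            [
                _species({"id": "a"}, annotation={"is": ["u1"]}),
                _species(
                    {"id": "b", "name": "x"},
                    notes=["n"],
                    annotation={"hasPart": ["u2"]},
                ),
            ]
        )
        assert list(df.columns) == [
            "id",
            "name",
            "notes",
            "annotation_is",
            "annotation_hasPart",
        ]

    def test_mixed_component_kinds_rejected(self):
        records = [
            _species({"id": "a"}),
            EntityRecord(component="compartment", attributes={"id": "c"}),
        ]
        with pytest.raises(ValueError, match="mixed component"):
            tabulate_entities(records)

    def test_empty_input_zero_rows_zero_columns(self):
        df = tabulate_entities([])
        assert df.shape == (0, 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.fixed_dictionaries(
            {},
            optional={
                "name": st.sampled_from(["x", "y"]),
                "compartment": st.just("c1"),
                "sboTerm": st.just("SBO:1"),
            },
        ),
        min_size=1,
        max_size=8,
    )
)
def test_column_exists_iff_tag_defined(attr_dicts):
    """For every tag T: a column exists for T ⇔ at least one entity defines T."""
    records = [
        _species({"id": f"s{i}", **attrs}) for i, attrs in enumerate(attr_dicts)
    ]
    df = tabulate_entities(records)
    defined = {key for attrs in attr_dicts for key in attrs} | {"id"}
    assert set(df.columns) == defined
    for column in df.columns:
        assert df[column].notna().any()


class TestTabulateReactions:
    def _reaction(self, rid_attrs, refs):
        return EntityRecord(component="reaction", attributes=rid_attrs, refs=refs)

    def test_two_additional_columns_and_join_key(self):
        reaction = self._reaction(
            {"id": "r1"},
            [
                SpeciesRef("a", "Reactant", {"species": "a"}),
                SpeciesRef("b", "Reactant", {"species": "b"}),
                SpeciesRef("c", "Product", {"species": "c"}),
            ],
        )
        _, sir = tabulate_reactions([reaction])
        assert len(sir) == 3
        assert list(sir.columns)[-2:] == ["reaction_id", "role"]
        assert set(sir["reaction_id"]) == {"r1"}

    def test_reaction_without_modifiers_has_no_modifier_rows(self):
        reaction = self._reaction(
            {"id": "r1"}, [SpeciesRef("a", "Reactant", {"species": "a"})]
        )
        _, sir = tabulate_reactions([reaction])
        assert "Modifier" not in set(sir["role"])

    def test_reaction_id_fallback_metaid_then_generated(self, caplog):
        reactions = [
            self._reaction({"metaid": "m7"}, [SpeciesRef("a", "Reactant", {"species": "a"})]),
            self._reaction({}, [SpeciesRef("b", "Product", {"species": "b"})]),
        ]
        with caplog.at_level("WARNING"):
            _, sir = tabulate_reactions(reactions)
        assert list(sir["reaction_id"]) == ["m7", "reaction_1"]

    def test_row_count_matches_raw_reference_scan(self, fixture_file):
        path, text, _ = fixture_file(n_species=9, n_reactions=5, seed=61)
        tables = as_tables(path)
        assert len(tables.df_species_in_reactions) == raw_counts(text)["refs"]


class TestAsTables:
    def test_four_tables_and_row_counts(self, fixture_file):
        path, text, truth = fixture_file(n_species=7, n_reactions=3, seed=62)
        tables = as_tables(path)
        names = [name for name, _ in tables]
        assert names == [
            "df_compartments",
            "df_species",
            "df_reactions",
            "df_species_in_reactions",
        ]
        counts = raw_counts(text)
        assert len(tables.df_compartments) == counts["compartments"]
        assert len(tables.df_species) == counts["species"]
        assert len(tables.df_reactions) == counts["reactions"]

    def test_components_absent_from_file_yield_empty_tables(self, fixture_file):
        path, _, _ = fixture_file(n_compartments=1, n_species=0, n_reactions=0, seed=63)
        tables = as_tables(path)
        assert len(tables.df_compartments) == 1
        for df in (tables.df_species, tables.df_reactions, tables.df_species_in_reactions):
            assert df.shape == (0, 0)

    def test_path_and_document_inputs_agree(self, fixture_file):
        path, _, _ = fixture_file(n_species=5, n_reactions=2, seed=64)
        via_path = as_tables(path)
        via_doc = as_tables(read_sbml(path))
        for (_, df_a), (_, df_b) in zip(via_path, via_doc):
            pd.testing.assert_frame_equal(df_a, df_b)

    def test_determinism_identical_bytes_identical_tables(self, fixture_file):
        path, _, _ = fixture_file(n_species=6, n_reactions=3, seed=65)
        for (_, df_a), (_, df_b) in zip(as_tables(path), as_tables(path)):
            pd.testing.assert_frame_equal(df_a, df_b)


class TestWriters:
    def test_csv_round_trip_and_empty_missing_fields(self, fixture_file, tmp_path):
        path, _, _ = fixture_file(n_species=6, n_reactions=3, seed=66)
        tables = as_tables(path)
        written = write_tables(tables, tmp_path / "out", fmt="csv")
        assert [p.name for p in written] == [
            "df_compartments.csv",
            "df_species.csv",
            "df_reactions.csv",
            "df_species_in_reactions.csv",
        ]
        reloaded = pd.read_csv(
            tmp_path / "out" / "df_species.csv", dtype="object", keep_default_na=False
        )
        assert reloaded.shape == tables.df_species.shape
        original = tables.df_species.fillna("")
        pd.testing.assert_frame_equal(reloaded, original, check_names=False)

    def test_tsv_delimiter(self, fixture_file, tmp_path):
        path, _, _ = fixture_file(n_species=3, n_reactions=1, seed=67)
        write_tables(as_tables(path), tmp_path, fmt="tsv")
        header = (tmp_path / "df_species.tsv").read_text().splitlines()[0]
        assert "\t" in header and "," not in header

    def test_csv_quotes_cells_containing_delimiter(self, tmp_path):
        df_input = tabulate_entities([_species({"id": "a", "name": 'x, "y"'})])
        from sbmlflat import TableSet

        tables = TableSet(df_input, df_input, df_input, df_input)
        write_tables(tables, tmp_path, components=("species",))
        reloaded = pd.read_csv(tmp_path / "df_species.csv", dtype="object")
        assert reloaded.loc[0, "name"] == 'x, "y"'

    def test_unknown_format_rejected(self, ahr_tables, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_tables(ahr_tables, tmp_path, fmt="xlsx")
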