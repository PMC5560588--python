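"""Gene, disease, and aging-term dictionary construction."""

import pandas as pd
import pytest

from agemine.dictionaries import (
    DictionaryError,
    GeneRecord,
    build_disease_dictionary,
    build_gene_dictionary,
    build_neighbor_word_sets,
    default_stoplist,
    load_aging_terms,
    write_gene_dictionary,
)


def _gene_row(gene_id, symbol, synonyms="-", description="-", gene_type="protein-coding"):
    return {
        "GeneID": gene_id,
        "Symbol": symbol,
        "Synonyms": synonyms,
        "description": description,
        "type_of_gene": gene_type,
    }


class TestGeneDictionary:
    def test_alk_full_names_collected(self, alk_gene_table):
        genes = build_gene_dictionary(alk_gene_table)
        assert genes["238"].full_names == {
            "anaplastic lymphoma receptor tyrosine kinase",
            "CD246 antigen",
            "mutant anaplastic lymphoma kinase",
        }
        assert genes["238"].primary_symbol == "ALK"
        assert "CD246" in genes["238"].aliases

    def test_alias_equal_to_other_primary_symbol_is_deleted(self):
        table = pd.DataFrame(
            [
                _gene_row("1", "ALK", synonyms="CD246"),
                _gene_row("2", "OTHER", synonyms="ALK|XYZ9"),
            ]
        )
        genes = build_gene_dictionary(table)
        assert "ALK" not in genes["2"].aliases
        assert genes["2"].aliases == {"XYZ9"}
        assert genes["1"].aliases == {"CD246"}  # owner unchanged

    def test_non_protein_coding_rows_filtered(self):
        table = pd.DataFrame(
            [
                _gene_row("1", "AAA1"),
                _gene_row("2", "BBB1", gene_type="ncRNA"),
            ]
        )
        assert set(build_gene_dictionary(table)) == {"1"}

    def test_ambiguous_alias_dropped_under_default_config(self):
        table = pd.DataFrame(
            [
                _gene_row("1", "AAA1", synonyms="SHARED"),
                _gene_row("2", "BBB1", synonyms="SHARED"),
            ]
        )
        genes = build_gene_dictionary(table)
        assert genes["1"].aliases == genes["2"].aliases == frozenset()
        multi = build_gene_dictionary(table, allow_multi_mapping=True)
        assert "SHARED" in multi["1"].aliases and "SHARED" in multi["2"].aliases

    def test_conflict_resolution_idempotent(self):
        table = pd.DataFrame(
            [
                _gene_row("1", "ALK", synonyms="CD246"),
                _gene_row("2", "OTHER", synonyms="ALK|XYZ9"),
                _gene_row("3", "THIRD", synonyms="OTHER|QQQ7"),
            ]
        )
        once = build_gene_dictionary(table)
        # rebuild from the resolved dictionary: nothing further changes
        rows = [
            _gene_row(g.gene_id, g.primary_symbol, "|".join(sorted(g.aliases)) or "-")
            for g in once.values()
        ]
        twice = build_gene_dictionary(pd.DataFrame(rows))
        assert {g: r.aliases for g, r in once.items()} == {
            g: r.aliases for g, r in twice.items()
        }

    def test_no_alias_equals_foreign_primary_symbol(self):
        table = pd.DataFrame(
            [
                _gene_row("1", "AAA1", synonyms="BBB1|UNQ1"),
                _gene_row("2", "BBB1", synonyms="AAA1|UNQ2"),
                _gene_row("3", "CCC1", synonyms="AAA1|BBB1|UNQ3"),
            ]
        )
        genes = build_gene_dictionary(table)
        primaries = {g.primary_symbol: g.gene_id for g in genes.values()}
        for record in genes.values():
            for alias in record.aliases:
                assert alias not in primaries

    def test_missing_column_and_duplicate_id_are_errors(self):
        with pytest.raises(DictionaryError, match="Synonyms"):
            build_gene_dictionary(
                pd.DataFrame([{"GeneID": "1", "Symbol": "A",
                               "description": "-", "type_of_gene": "protein-coding"}])
            )
        dupes = pd.DataFrame([_gene_row("1", "AAA1"), _gene_row("1", "AAA2")])
        with pytest.raises(DictionaryError, match="duplicate"):
            build_gene_dictionary(dupes)

    def test_export_flags_primary_vs_synonym(self, alk_gene_table, tmp_path):
        genes = build_gene_dictionary(alk_gene_table)
        out = tmp_path / "genes.tsv"
        write_gene_dictionary(genes, out)
        table = pd.read_csv(out, sep="\t")
        flags = dict(zip(table["Surface"], table["Synonym"]))
        assert flags["ALK"] == 1
        assert flags["CD246"] == 0


class TestNeighborWordSets:
    def test_alk_worked_example(self, alk_gene_table):
        genes = build_gene_dictionary(alk_gene_table)
        sets = build_neighbor_word_sets(genes, stoplist=default_stoplist())
        assert sets["238"].words == {"anaplastic", "lymphoma", "cd246"}

    def test_single_stoplisted_name_gives_empty_set(self):
        gene = GeneRecord("9", "KIN1", frozenset(), frozenset({"kinase"}))
        sets = build_neighbor_word_sets([gene], stoplist={"kinase"})
        assert sets["9"].words == frozenset()

    def test_union_over_names_and_order_insensitivity(self):
        a = GeneRecord("1", "SYM1", frozenset(), frozenset({"alpha beta", "beta gamma"}))
        b = GeneRecord("2", "SYM2", frozenset(), frozenset({"beta gamma", "alpha beta"}))
        sets = build_neighbor_word_sets([a, b], stoplist=set(), min_word_len=3)
        assert sets["1"].words == {"alpha", "beta", "gamma"} == sets["2"].words

    def test_min_word_len_and_own_symbol_excluded(self):
        gene = GeneRecord("1", "ABC", frozenset(), frozenset({"abc xy longword"}))
        sets = build_neighbor_word_sets([gene], stoplist=set(), min_word_len=3)
        assert sets["1"].words == {"longword"}

    def test_frequency_rule_drops_widespread_words(self):
        genes = [
            GeneRecord(str(i), f"S{i}", frozenset(), frozenset({f"common word{i}"}))
            for i in range(5)
        ]
        sets = build_neighbor_word_sets(genes, stoplist=set(), max_gene_frequency=3)
        for i in range(5):
            assert "common" not in sets[str(i)].words
            assert f"word{i}" in sets[str(i)].words


class TestDiseaseDictionary:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows,
            columns=["DiseaseName", "DiseaseID", "Synonyms", "SlimMappings"],
        )

    def test_shared_synonym_dropped_from_both(self):
        table = self._table(
            [
                ("Alzheimer Disease", "MESH:D000544", "AD|Alzheimer dementia", "-"),
                ("Atopic Dermatitis", "MESH:D003876", "AD|eczema atopic", "-"),
            ]
        )
        diseases = build_disease_dictionary(table, general_word_list=set())
        assert "AD" not in diseases["MESH:D000544"].surface_forms
        assert "AD" not in diseases["MESH:D003876"].surface_forms
        assert "eczema atopic" in diseases["MESH:D003876"].surface_forms

    def test_animal_disease_rows_excluded(self):
        table = self._table(
            [
                ("Bovine Mastitis", "MESH:D008413", "-", "Animal disease"),
                ("Stroke", "MESH:D020521", "brain attack", "Cardiovascular disease"),
            ]
        )
        diseases = build_disease_dictionary(table, general_word_list=set())
        assert set(diseases) == {"MESH:D020521"}

    def test_general_word_synonym_removed_canonical_kept(self):
        table = self._table(
            [("Stroke", "MESH:D020521", "stroke|cerebral infarct", "-")]
        )
        diseases = build_disease_dictionary(table, general_word_list={"stroke"})
        record = diseases["MESH:D020521"]
        assert record.canonical_form == "Stroke"
        assert "Stroke" in record.surface_forms
        assert "stroke" not in record.surface_forms - {"Stroke"}
        assert "cerebral infarct" in record.surface_forms

    def test_rows_without_mesh_or_omim_id_dropped(self):
        table = self._table(
            [("Madeup Disease", "XYZ:123", "-", "-"),
             ("Real Disease", "OMIM:600000", "-", "-")]
        )
        assert set(build_disease_dictionary(table, general_word_list=set())) == {
            "OMIM:600000"
        }


class TestAgingTerms:
    def test_packaged_fixture_has_45_terms(self):
        assert len(load_aging_terms()) == 45

    def test_duplicates_collapse_and_case_insensitive_ids(self):
        records = load_aging_terms(["AGING", "aging", "Senescence"])
        assert set(records) == {"AGING", "SENESCENCE"}

    def test_empty_list_is_an_error(self):
        with pytest.raises(DictionaryError):
            load_aging_terms([" ", ""])
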