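"""Co-occurrence counting, gene calling, and coverage curves."""

import pandas as pd
import pytest

import agemine as am
from agemine import synthetic as syn
from agemine.cooccurrence import (
    cooccurrences,
    genes_with_all_terms,
    identify_aging_genes,
    per_term_gene_counts,
    per_term_gene_sets,
    term_coverage_curve,
)
from conftest import pairs_as_dict


def occ(rows):
    table = pd.DataFrame(rows, columns=["entity_id", "doc_id", "sentence_index"])
    return table


class TestCooccurrences:
    def test_same_sentence_counts_at_both_scopes(self):
        gene = occ([("G", "d1", 0)])
        term = occ([("T", "d1", 0)])
        for scope in ("sentence", "abstract"):
            pairs = cooccurrences(gene, term, scope)
            assert pairs_as_dict(pairs) == {("G", "T"): 1}

    def test_different_sentences_count_at_abstract_scope_only(self):
        gene = occ([("G", "d1", 0)])
        term = occ([("T", "d1", 2)])
        assert cooccurrences(gene, term, "sentence").empty
        assert pairs_as_dict(cooccurrences(gene, term, "abstract")) == {("G", "T"): 1}

    def test_doc_count_is_distinct_documents_not_hits(self):
        gene = occ([("G", "d1", 0), ("G", "d1", 1), ("G", "d2", 0)])
        term = occ([("T", "d1", 0), ("T", "d1", 1), ("T", "d2", 0)])
        assert pairs_as_dict(cooccurrences(gene, term, "sentence")) == {("G", "T"): 2}

    def test_symmetric_in_entity_roles(self):
        gene = occ([("G", "d1", 0), ("G", "d2", 1)])
        term = occ([("T", "d1", 0), ("T", "d2", 0)])
        ab = pairs_as_dict(cooccurrences(gene, term, "abstract"))
        ba = pairs_as_dict(cooccurrences(term, gene, "abstract"))
        assert ab == {(a, b): c for (b, a), c in ba.items()}

    def test_mismatched_stores_rejected(self):
        gene, term = occ([("G", "d1", 0)]), occ([("T", "d1", 0)])
        gene.attrs["store_id"] = "aaa"
        term.attrs["store_id"] = "bbb"
        with pytest.raises(ValueError, match="different stores"):
            cooccurrences(gene, term, "sentence")

    def test_planted_doc_counts_match_brute_force(self, run_pipeline):
        spec = syn.random_corpus_spec(seed=21, n_docs=40)
        text, truth = syn.generate_corpus(spec)
        result = run_pipeline(text)
        for scope in ("sentence", "abstract"):
            assert pairs_as_dict(result["pairs"][scope]) == truth.expected_pairs(scope)


class TestGeneCalling:
    def test_gene_paired_only_with_disease_excluded(self):
        pairs = cooccurrences(occ([("G", "d1", 0)]), occ([("MESH:D1", "d1", 0)]), "sentence")
        assert identify_aging_genes(pairs, {"LONGEVITY"}) == {}

    def test_evidence_lists_terms_with_doc_counts(self):
        gene = occ([("G", f"d{i}", 0) for i in range(3)])
        term = occ([("LONGEVITY", f"d{i}", 0) for i in range(3)])
        pairs = cooccurrences(gene, term, "sentence")
        assert identify_aging_genes(pairs, {"LONGEVITY"}) == {"G": {"LONGEVITY": 3}}

    def test_abstract_scope_calls_superset_of_sentence_scope(self, run_pipeline):
        spec = syn.random_corpus_spec(seed=33)
        text, _ = syn.generate_corpus(spec)
        result = run_pipeline(text)
        terms = set(syn.DEFAULT_TERMS)
        called = {
            scope: set(identify_aging_genes(result["pairs"][scope], terms))
            for scope in ("sentence", "abstract")
        }
        assert called["sentence"] <= called["abstract"]

    def test_end_to_end_recall_no_false_negatives(self, run_pipeline):
        """Every planted sentence-scope association yields a called gene."""
        spec = syn.SyntheticCorpusSpec(
            n_docs=25,
            planted_associations=(
                ("G001", "AGING", "sentence", 2),
                ("G005", "HEALTHSPAN", "sentence", 1),
                ("G009", "LONG-LIVED", "sentence", 3),
            ),
            seed=4,
        )
        text, truth = syn.generate_corpus(spec)
        called = set(
            identify_aging_genes(run_pipeline(text)["pairs"]["sentence"], set(syn.DEFAULT_TERMS))
        )
        assert called == truth.expected_genes("sentence") == {"G001", "G005", "G009"}


class TestPerTermCounts:
    def test_absent_term_counts_zero(self):
        pairs = cooccurrences(occ([("G", "d1", 0)]), occ([("AGING", "d1", 0)]), "sentence")
        counts = per_term_gene_counts(pairs, ["AGING", "AGEING-SUPPRESSOR"])
        table = dict(zip(counts["term_id"], counts["n_genes"]))
        assert table == {"AGING": 1, "AGEING-SUPPRESSOR": 0}

    def test_planted_per_term_sets_recovered(self, run_pipeline):
        spec = syn.random_corpus_spec(seed=8)
        text, truth = syn.generate_corpus(spec)
        result = run_pipeline(text)
        for scope in ("sentence", "abstract"):
            got = per_term_gene_sets(result["pairs"][scope], set(syn.DEFAULT_TERMS))
            expected = truth.expected_term_gene_sets(scope)
            assert {t: s for t, s in got.items() if s} == expected

    def test_sentence_counts_bounded_by_abstract_counts(self, run_pipeline):
        spec = syn.random_corpus_spec(seed=17)
        text, _ = syn.generate_corpus(spec)
        result = run_pipeline(text)
        terms = sorted(syn.DEFAULT_TERMS)
        sent = per_term_gene_counts(result["pairs"]["sentence"], terms)["n_genes"]
        abst = per_term_gene_counts(result["pairs"]["abstract"], terms)["n_genes"]
        assert (sent <= abst).all()


class TestCoverageCurve:
    SETS = {"A": {1, 2}, "B": {2, 3}, "C": {3}}

    def test_explicit_order_cumulative_counts(self):
        _, curve = term_coverage_curve(self.SETS, ordering=["A", "B", "C"])
        assert curve == [2, 3, 3]

    def test_final_value_is_union_size_for_any_order(self):
        import itertools

        for perm in itertools.permutations(self.SETS):
            _, curve = term_coverage_curve(self.SETS, ordering=list(perm))
            assert curve[-1] == 3

    def test_greedy_picks_largest_set_first_and_breaks_ties_alphabetically(self):
        order, curve = term_coverage_curve(self.SETS)
        assert order[0] == "A"  # largest set
        assert curve == [2, 3, 3]
        tied = {"B": {1}, "A": {2}}
        order, _ = term_coverage_curve(tied)
        assert order == ["A", "B"]


class TestGenesWithAllTerms:
    def test_intersection_semantics(self):
        gene = occ(
            [("G1", "d1", 0), ("G1", "d2", 0), ("G2", "d1", 0)]
        )
        term = occ(
            [("AGING", "d1", 0), ("LONGEVITY", "d2", 0), ("LONGEVITY", "d1", 1)]
        )
        pairs = cooccurrences(gene, term, "abstract")
        assert genes_with_all_terms(pairs, ["AGING", "LONGEVITY"]) == {"G1", "G2"}
        assert genes_with_all_terms(pairs, ["AGING"]) == {"G1", "G2"}

    def test_missing_one_term_excludes_gene(self):
        gene = occ([("G1", "d1", 0)])
        term = occ([("AGING", "d1", 0), ("LONGEVITY", "d9", 0)])
        pairs = cooccurrences(gene, term, "abstract")
        assert genes_with_all_terms(pairs, ["AGING", "LONGEVITY"]) == set()

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError):
            genes_with_all_terms(pd.DataFrame(columns=["entity_a", "entity_b", "scope", "doc_count"]), [])

    def test_matches_brute_force_intersection_on_planted_corpus(self, run_pipeline):
        spec = syn.SyntheticCorpusSpec(
            n_docs=20,
            planted_associations=(
                ("G001", "AGING", "abstract", 2),
                ("G001", "LONGEVITY", "sentence", 1),
                ("G002", "AGING", "abstract", 1),
            ),
            seed=6,
        )
        text, truth = syn.generate_corpus(spec)
        pairs = run_pipeline(text)["pairs"]["abstract"]
        sets = truth.expected_term_gene_sets("abstract")
        expected = sets.get("AGING", set()) & sets.get("LONGEVITY", set())
        assert genes_with_all_terms(pairs, ["AGING", "LONGEVITY"]) == expected == {"G001"}
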