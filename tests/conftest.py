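import pandas as pd
import pytest

import agemine as am
from agemine import synthetic as syn


@pytest.fixture
def alk_gene_table() -> pd.DataFrame:
    """The ALK record with its three full gene names."""
    return pd.DataFrame(
        [
            {
                "GeneID": "238",
                "Symbol": "ALK",
                "Synonyms": "CD246|NBLST3",
                "description": "anaplastic lymphoma receptor tyrosine kinase",
                "Other_designations": "CD246 antigen|mutant anaplastic lymphoma kinase",
                "type_of_gene": "protein-coding",
            }
        ]
    )


@pytest.fixture
def full_pool() -> dict:
    """Default synthetic gene pool plus the ambiguous-symbol gene."""
    pool = syn.default_gene_pool()
    ambiguous = syn.make_ambiguous_gene()
    pool[ambiguous.gene_id] = ambiguous
    return pool


@pytest.fixture
def run_pipeline(full_pool):
    """Run ingest -> match -> (neighbor filter) -> cooccur on corpus text.

    Returns a dict with the store, raw and filtered gene occurrences, term
    occurrences, and pair tables at both scopes.
    """

    def _run(text: str, neighbor: bool = True) -> dict:
        store = am.ingest_corpus(text)
        gene_dict = syn.gene_records(full_pool)
        term_dict = syn.term_records(syn.DEFAULT_TERMS)
        gene_occ = am.keyword_match(store, gene_dict)
        term_occ = am.keyword_match(store, term_dict)
        neighbor_sets = am.build_neighbor_word_sets(
            gene_dict, stoplist=am.default_stoplist()
        )
        filtered = (
            am.neighbor_filter(gene_occ, store, neighbor_sets)
            if neighbor
            else gene_occ
        )
        return {
            "store": store,
            "gene_occ": gene_occ,
            "filtered": filtered,
            "term_occ": term_occ,
            "pairs": {
                scope: am.cooccurrences(filtered, term_occ, scope)
                for scope in ("sentence", "abstract")
            },
        }

    return _run


def pairs_as_dict(pairs: pd.DataFrame) -> dict:
    return {
        (row.entity_a, row.entity_b): int(row.doc_count)
        for row in pairs.itertuples(index=False)
    }
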