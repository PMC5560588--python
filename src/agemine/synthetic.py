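"""Synthetic abstract corpora with exact ground truth.

The full pipeline is exercised against generated MEDLINE-like corpora in
which every gene mention, term mention, and gene–term co-occurrence is
planted deliberately:

* *sentence-scope* plants put a gene symbol (with one of its neighbor
  words) and an aging term into one sentence of a document;
* *abstract-scope* plants put them into two different sentences of the
  same document, so the association is visible at abstract scope only;
* *ambiguous symbols* (gene symbols that collide with English words, like
  IMPACT) appear both as true mentions — neighbor word present — and as
  English-word decoys co-located with an aging term, at a configurable
  decoy rate; the decoys degrade keyword-only precision and are exactly
  what the neighbor filter must remove;
* *decoy documents* contain filler sentences and no true gene mention.

Gene symbols (``ZGX1`` ...) and neighbor words (``belnepine`` ...) are
synthesized so they cannot collide with template or filler text, which
makes the ground truth exact: the expected pipeline output is computable
from the planted mention lists alone.  Everything is driven by one
``random.Random(seed)``; the same spec and seed yield a byte-identical
corpus.
"""

from __future__ import annotations

import json
import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .dictionaries import GeneRecord, TermRecord

# --------------------------------------------------------------------------
# synthetic vocabulary

_SYLLABLES = (
    "bel", "cor", "dal", "fen", "gor", "hul", "jin", "kel", "lom", "mur",
    "nep", "per", "quo", "rin", "sul", "tor", "vex", "wil", "yor", "zan",
)


def _coined_word(i: int) -> str:
    a = _SYLLABLES[i % len(_SYLLABLES)]
    b = _SYLLABLES[(i // len(_SYLLABLES) + 7) % len(_SYLLABLES)]
    return a + b + "ine"


@dataclass(frozen=True)
class SyntheticGene:
    """A generated gene: symbol, aliases, full names, known neighbor words."""

    gene_id: str
    symbol: str
    aliases: tuple[str, ...]
    full_names: tuple[str, ...]
    neighbor_words: tuple[str, ...]


def default_gene_pool(n_genes: int = 16) -> dict[str, SyntheticGene]:
    """Deterministic pool of well-behaved synthetic genes."""
    pool: dict[str, SyntheticGene] = {}
    for i in range(n_genes):
        w1, w2 = _coined_word(2 * i), _coined_word(2 * i + 1)
        gene = SyntheticGene(
            gene_id=f"G{i + 1:03d}",
            symbol=f"ZGX{i + 1}",
            aliases=(f"ZGA{i + 1}",),
            full_names=(f"{w1} {w2} kinase", f"{w1} homolog"),
            neighbor_words=(w1, w2),
        )
        pool[gene.gene_id] = gene
    return pool


def make_ambiguous_gene(
    symbol: str = "IMPACT", gene_id: str = "A001"
) -> SyntheticGene:
    """A gene whose symbol collides with an ordinary English word.

    Modeled on the classic offender: a symbol that reads as a common noun,
    whose full name still yields informative neighbor words.
    """
    return SyntheticGene(
        gene_id=gene_id,
        symbol=symbol,
        aliases=(),
        full_names=("imprinted and ancient homolog",),
        neighbor_words=("imprinted", "ancient"),
    )


#: Default aging-term vocabulary used by generated corpora: term id -> the
#: surface string written into sentences (matching is case-insensitive).
DEFAULT_TERMS: dict[str, str] = {
    "AGING": "aging",
    "SENESCENCE": "senescence",
    "LONGEVITY": "longevity",
    "LIFESPAN": "lifespan",
    "LONG-LIVED": "long-lived",
    "ANTI-AGING": "anti-aging",
    "AGE-RELATED": "age-related",
    "HEALTHSPAN": "healthspan",
}

#: Filler sentences: disjoint from every symbol, term surface, and coined
#: neighbor word, so they can never create accidental dictionary hits.
FILLER_SENTENCES = (
    "The cohort was followed across several scheduled visits.",
    "Samples were processed under a standard operating procedure.",
    "Results were compared between the two study arms.",
    "No additional covariates were considered in the primary model.",
    "Measurements were repeated in duplicate by trained staff.",
    "Baseline characteristics were balanced between groups.",
    "Statistical analyses used a two-sided significance threshold.",
    "Data quality was reviewed before the main analysis.",
    "Recruitment took place at three participating centres.",
    "Follow-up questionnaires were completed by most participants.",
)


def gene_records(genes: Mapping[str, SyntheticGene]) -> dict[str, GeneRecord]:
    """View a synthetic pool as dictionary GeneRecords."""
    return {
        g.gene_id: GeneRecord(
            gene_id=g.gene_id,
            primary_symbol=g.symbol,
            aliases=frozenset(g.aliases),
            full_names=frozenset(g.full_names),
        )
        for g in genes.values()
    }


def term_records(terms: Mapping[str, str]) -> dict[str, TermRecord]:
    """View a term_id -> surface mapping as dictionary TermRecords."""
    return {
        term_id: TermRecord(
            term_id=term_id,
            canonical_form=surface,
            surface_forms=frozenset({surface}),
            category="aging-term",
        )
        for term_id, surface in terms.items()
    }


# --------------------------------------------------------------------------
# corpus specification

Plant = tuple[str, str, str, int]  # (gene_id, term_id, scope, n_docs_joint)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of one generated corpus.

    ``planted_associations`` holds (gene_id, term_id, scope, n_docs_joint)
    tuples; each joint document hosts exactly one plant, so ground-truth
    co-occurrence counts equal the planted counts.  ``ambiguous_symbols``
    holds (symbol, decoy_rate) pairs; each such symbol makes
    ``ambiguous_appearances`` appearances in decoy documents, the given
    fraction of them as English-word decoys next to an aging term.
    """

    n_docs: int
    planted_associations: tuple[Plant, ...] = ()
    ambiguous_symbols: tuple[tuple[str, float], ...] = ()
    decoy_doc_fraction: float = 0.0
    sentences_per_doc: tuple[int, int] = (3, 6)
    ambiguous_appearances: int = 4
    seed: int = 0

    @property
    def n_decoy_docs(self) -> int:
        return round(self.decoy_doc_fraction * self.n_docs)

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be positive")
        if not 0.0 <= self.decoy_doc_fraction <= 1.0:
            raise ValueError("decoy_doc_fraction must lie in [0, 1]")
        lo, hi = self.sentences_per_doc
        if not 1 <= lo <= hi:
            raise ValueError("sentences_per_doc must be a nonempty range")
        total_joint = sum(p[3] for p in self.planted_associations)
        for gene_id, term_id, scope, joint in self.planted_associations:
            if scope not in ("sentence", "abstract"):
                raise ValueError(f"unknown plant scope: {scope!r}")
            if joint < 1 or joint > self.n_docs:
                raise ValueError(
                    f"plant ({gene_id}, {term_id}): joint count {joint} "
                    f"infeasible for {self.n_docs} documents"
                )
        if total_joint > self.n_docs - self.n_decoy_docs:
            raise ValueError(
                f"infeasible spec: {total_joint} planted documents requested "
                f"but only {self.n_docs - self.n_decoy_docs} non-decoy "
                "documents available"
            )
        for symbol, rate in self.ambiguous_symbols:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"collision rate for {symbol} must lie in [0, 1]")
        if self.ambiguous_symbols and self.ambiguous_appearances > 0:
            if self.n_decoy_docs == 0:
                raise ValueError(
                    "ambiguous symbols need decoy documents to live in; "
                    "set decoy_doc_fraction > 0"
                )


# --------------------------------------------------------------------------
# ground truth

Mention = tuple[str, str, int]  # (entity_id, doc_id, sentence_index)


@dataclass
class GroundTruth:
    """Exact record of what was planted where.

    The *expected* pipeline output is derived from true gene mentions and
    all term mentions; the keyword-only baseline additionally sees the
    false (decoy) gene mentions.
    """

    seed: int
    doc_ids: list[str]
    sentences: dict[str, list[str]]
    true_gene_mentions: set[Mention] = field(default_factory=set)
    false_gene_mentions: set[Mention] = field(default_factory=set)
    term_mentions: set[Mention] = field(default_factory=set)

    def _pairs(
        self, gene_mentions: Iterable[Mention], scope: str
    ) -> dict[tuple[str, str], int]:
        term_by_doc: dict[str, set[tuple[str, int]]] = defaultdict(set)
        for term_id, doc_id, sent in self.term_mentions:
            term_by_doc[doc_id].add((term_id, sent))
        docs: dict[tuple[str, str], set[str]] = defaultdict(set)
        for gene_id, doc_id, sent in gene_mentions:
            for term_id, term_sent in term_by_doc.get(doc_id, ()):
                if scope == "abstract" or sent == term_sent:
                    docs[(gene_id, term_id)].add(doc_id)
        return {pair: len(doc_set) for pair, doc_set in docs.items()}

    def expected_pairs(self, scope: str) -> dict[tuple[str, str], int]:
        """Gene–term doc counts a correct, neighbor-filtered pipeline finds."""
        return self._pairs(self.true_gene_mentions, scope)

    def keyword_pairs(self, scope: str) -> dict[tuple[str, str], int]:
        """Doc counts a keyword-only pipeline (no neighbor filter) finds."""
        return self._pairs(
            self.true_gene_mentions | self.false_gene_mentions, scope
        )

    def expected_genes(self, scope: str) -> set[str]:
        return {gene for gene, _ in self.expected_pairs(scope)}

    def expected_term_gene_sets(self, scope: str) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = defaultdict(set)
        for (gene, term), _ in self.expected_pairs(scope).items():
            sets[term].add(gene)
        return dict(sets)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"# seed={self.seed}\n")
            handle.write("kind\tentity_id\tdoc_id\tsentence_index\n")
            rows = (
                [("gene_true", *m) for m in sorted(self.true_gene_mentions)]
                + [("gene_false", *m) for m in sorted(self.false_gene_mentions)]
                + [("term", *m) for m in sorted(self.term_mentions)]
            )
            for kind, entity, doc, sent in rows:
                handle.write(f"{kind}\t{entity}\t{doc}\t{sent}\n")


# --------------------------------------------------------------------------
# corpus generation

_Event = tuple  # ("gene", gene_id, is_true) | ("term", term_id)


def _insert(rng: random.Random, doc: list, item) -> None:
    doc.insert(rng.randrange(len(doc) + 1), item)


def generate_corpus(
    spec: SyntheticCorpusSpec,
    genes: Mapping[str, SyntheticGene] | None = None,
    terms: Mapping[str, str] | None = None,
    dialect: str = "simple",
) -> tuple[str, GroundTruth]:
    """Realize a corpus spec as text plus its exact ground truth.

    ``dialect`` selects the output format: ``"simple"`` (one JSON record
    per line) or ``"medline"`` (PMID/AB flat-file records).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    if genes is None:
        genes = default_gene_pool()
        if spec.ambiguous_symbols:
            amb = make_ambiguous_gene()
            genes = {**genes, amb.gene_id: amb}
    if terms is None:
        terms = dict(DEFAULT_TERMS)
    symbol_to_gene = {g.symbol: g for g in genes.values()}

    for gene_id, term_id, _, _ in spec.planted_associations:
        if gene_id not in genes:
            raise KeyError(f"plant references unknown gene {gene_id}")
        if term_id not in terms:
            raise KeyError(f"plant references unknown term {term_id}")
    for symbol, _ in spec.ambiguous_symbols:
        if symbol not in symbol_to_gene:
            raise KeyError(f"ambiguous symbol {symbol} has no gene in the pool")

    doc_ids = [str(20_000_001 + i) for i in range(spec.n_docs)]
    indices = list(range(spec.n_docs))
    decoy_indices = sorted(rng.sample(indices, spec.n_decoy_docs))
    plant_pool = [i for i in indices if i not in set(decoy_indices)]
    rng.shuffle(plant_pool)

    docs: dict[int, list[tuple[str, list[_Event]]]] = {}
    for i in indices:
        n_filler = rng.randint(*spec.sentences_per_doc)
        docs[i] = [(rng.choice(FILLER_SENTENCES), []) for _ in range(n_filler)]

    for gene_id, term_id, scope, joint in spec.planted_associations:
        gene = genes[gene_id]
        surface = terms[term_id]
        for _ in range(joint):
            host = plant_pool.pop()
            word = rng.choice(gene.neighbor_words)
            if scope == "sentence":
                text = (
                    f"In this study the {gene.symbol} gene, encoding a "
                    f"{word} product, was linked to {surface}."
                )
                _insert(
                    rng,
                    docs[host],
                    (text, [("gene", gene_id, True), ("term", term_id)]),
                )
            else:
                gene_text = (
                    f"The {gene.symbol} gene, encoding a {word} product, "
                    "was profiled here."
                )
                term_text = (
                    f"Participants showed marked {surface} over follow-up."
                )
                _insert(rng, docs[host], (gene_text, [("gene", gene_id, True)]))
                _insert(rng, docs[host], (term_text, [("term", term_id)]))

    for symbol, rate in spec.ambiguous_symbols:
        gene = symbol_to_gene[symbol]
        total = spec.ambiguous_appearances
        n_false = round(rate * total)
        for _ in range(n_false):
            host = rng.choice(decoy_indices)
            term_id = rng.choice(sorted(terms))
            text = (
                f"The {symbol} of dietary restriction on {terms[term_id]} "
                "outcomes was reviewed."
            )
            _insert(
                rng,
                docs[host],
                (text, [("gene", gene.gene_id, False), ("term", term_id)]),
            )
        for _ in range(total - n_false):
            host = rng.choice(decoy_indices)
            word = rng.choice(gene.neighbor_words)
            text = f"The {symbol} gene, encoding a {word} product, was sequenced."
            _insert(rng, docs[host], (text, [("gene", gene.gene_id, True)]))

    truth = GroundTruth(
        seed=spec.seed,
        doc_ids=list(doc_ids),
        sentences={
            doc_ids[i]: [text for text, _ in docs[i]] for i in indices
        },
    )
    for i in indices:
        for sent_index, (_, events) in enumerate(docs[i]):
            for event in events:
                if event[0] == "gene":
                    mention = (event[1], doc_ids[i], sent_index)
                    if event[2]:
                        truth.true_gene_mentions.add(mention)
                    else:
                        truth.false_gene_mentions.add(mention)
                else:
                    truth.term_mentions.add((event[1], doc_ids[i], sent_index))

    abstracts = {
        doc_id: " ".join(sentences)
        for doc_id, sentences in truth.sentences.items()
    }
    if dialect == "simple":
        text = "\n".join(
            json.dumps({"id": doc_id, "abstract": abstracts[doc_id]})
            for doc_id in doc_ids
        )
    elif dialect == "medline":
        blocks = [
            f"PMID- {doc_id}\nAB  - {abstracts[doc_id]}\n" for doc_id in doc_ids
        ]
        text = "\n".join(blocks)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return text + "\n", truth


def random_corpus_spec(
    seed: int,
    n_docs: int = 50,
    genes: Mapping[str, SyntheticGene] | None = None,
    terms: Mapping[str, str] | None = None,
) -> SyntheticCorpusSpec:
    """A randomized but always-feasible spec for property testing."""
    rng = random.Random(seed)
    gene_ids = sorted((genes or default_gene_pool()).keys())
    term_ids = sorted((terms or DEFAULT_TERMS).keys())
    decoy_fraction = 0.2
    capacity = n_docs - round(decoy_fraction * n_docs)
    plants: list[Plant] = []
    used = 0
    for _ in range(rng.randint(4, 12)):
        joint = rng.randint(1, 2)
        if used + joint > capacity:
            break
        plants.append(
            (
                rng.choice(gene_ids),
                rng.choice(term_ids),
                rng.choice(("sentence", "abstract")),
                joint,
            )
        )
        used += joint
    return SyntheticCorpusSpec(
        n_docs=n_docs,
        planted_associations=tuple(plants),
        decoy_doc_fraction=decoy_fraction,
        seed=seed,
    )


# --------------------------------------------------------------------------
# gene table generation

GENE_TABLE_COLUMNS = [
    "GeneID",
    "Symbol",
    "Synonyms",
    "description",
    "Other_designations",
    "type_of_gene",
]


def generate_gene_table(
    n_genes: int,
    n_aliases: int = 1,
    collision_spec: Iterable[tuple[str, str]] | None = None,
    seed: int = 0,
    n_noncoding: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Emit an NCBI-style gene table with engineered alias collisions.

    ``collision_spec`` lists (owner_gene_id, victim_gene_id) pairs: the
    owner's primary symbol is planted as an alias of the victim, which the
    dictionary builder must strip again.  Returns the table and a ground
    truth dict recording the planted collisions.
    """
    rng = random.Random(seed)
    pool = default_gene_pool(n_genes)
    extra_aliases = {
        gene_id: tuple(
            f"ZGA{index + 1}X{j}" for j in range(1, n_aliases)
        )
        for index, gene_id in enumerate(pool)
    }
    collisions = list(collision_spec or [])
    planted: dict[str, list[str]] = defaultdict(list)
    for owner_id, victim_id in collisions:
        if owner_id not in pool or victim_id not in pool:
            raise KeyError("collision references a gene outside the table")
        planted[victim_id].append(pool[owner_id].symbol)

    rows = []
    for index, (gene_id, gene) in enumerate(pool.items()):
        aliases = list(gene.aliases[: max(0, min(n_aliases, len(gene.aliases)))])
        aliases += list(extra_aliases[gene_id])
        aliases += planted.get(gene_id, [])
        names = list(gene.full_names)
        rows.append(
            {
                "GeneID": gene.gene_id,
                "Symbol": gene.symbol,
                "Synonyms": "|".join(aliases) if aliases else "-",
                "description": names[0],
                "Other_designations": "|".join(names[1:]) if len(names) > 1 else "-",
                "type_of_gene": "protein-coding",
            }
        )
    for j in range(n_noncoding):
        rows.append(
            {
                "GeneID": f"N{j + 1:03d}",
                "Symbol": f"ZNC{j + 1}",
                "Synonyms": "-",
                "description": f"{_coined_word(400 + j)} antisense transcript",
                "Other_designations": "-",
                "type_of_gene": "ncRNA",
            }
        )
    rng.shuffle(rows)
    table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    truth = {
        "n_protein_coding": n_genes,
        "n_noncoding": n_noncoding,
        "collisions": {victim: sorted(syms) for victim, syms in planted.items()},
        "pool": pool,
    }
    return table, truth
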