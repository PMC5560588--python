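# Methods

## Model and assumptions

The pipeline treats "gene g is aging-related" as a literature hypothesis
supported by co-occurrence evidence: the more documents in which g's symbol
appears together with a curated aging-related term, the stronger the
support. Two co-occurrence scopes trade precision against recall:

* **sentence scope** — gene and term in one sentence. Joint mention within
  a sentence is strong evidence of a stated relationship.
* **abstract scope** — gene and term anywhere in one abstract. Catches
  relationships split across sentences at the cost of topical-only
  co-mention.

Both are counted as *distinct documents*, never within-document hit
multiplicities, so a single enthusiastic abstract cannot dominate. By
construction every sentence-scope count is bounded by the abstract-scope
count of the same pair, and the sentence-scope called gene set is contained
in the abstract-scope set; the test suite asserts this corpus-wide.

The major error source is gene-symbol homonymy: symbols are acronyms and
collide with English words and with other acronyms. The **neighbor search**
assumes that a genuine gene mention is accompanied, in the same sentence,
by at least one informative word from the gene's full names (the words the
acronym abbreviates). This is a high-precision heuristic: it cannot rescue
a true mention whose sentence never spells anything out, so it trades
recall for precision exactly where keyword search is weakest.

## Dictionary construction

* **Genes** (NCBI `gene_info`-style TSV): protein-coding rows only;
  synonyms split on `|`, `-` meaning empty. Conflicts: an alias equal to a
  *different* gene's primary symbol is deleted (the primary owner keeps
  it); under the default single-mapping configuration an alias shared by
  several genes is deleted from all of them, so each surviving surface form
  maps to exactly one gene. The resolution is idempotent. An optional
  multi-mapping mode emits one occurrence per candidate gene and lets the
  neighbor filter adjudicate.
* **Neighbor word sets**: full names are split at whitespace plus
  `,;:/()-`, lowercased; tokens shorter than 3 characters, the gene's own
  symbol, and stoplist members are removed. The shipped stoplist holds
  high-frequency biomedical name components (receptor, kinase, antigen,
  protein, factor, ...) that occur in the names of many genes and therefore
  identify none; it is configurable, and an optional frequency rule
  additionally drops any token occurring in the names of more than K genes
  (K = 50 by default when enabled). There is no objective boundary for
  "too generic"; the stoplist-plus-frequency rule is a reproducible proxy
  for that judgment.
* **Diseases** (CTD-style TSV): animal-disease rows (SlimMappings flag)
  removed; primary names must carry a `MESH:`/`OMIM:` identifier; synonyms
  mapping to more than one disease, or spelled like general English words
  (shipped configurable list), are deleted while canonical names are kept.
* **Aging terms**: 45 fixed surface strings shipped as a fixture, one per
  line, including spelling variants (AGING/AGEING) and hyphenation variants
  (LIFESPAN/LIFE-SPAN) as *separate* entries. Variants are matched
  literally — no hyphen normalization — because the list enumerates them
  explicitly and whole-token matching must keep AGING from firing inside
  "anti-aging".

### Case handling

Aging terms and disease names match case-insensitively. Gene symbols match
case-sensitively by default: symbols are acronym-like, and case is most of
the signal separating *IMPACT* from "impact". A configuration switch
(`case_sensitive=False`) exists for corpora with unreliable casing.

## Matching and filtering

A surface form hits a sentence only as a whole token: the neighboring
characters may not be alphanumeric or hyphen, and multiword forms match as
contiguous token sequences. The neighbor filter retains a gene occurrence
iff one of its neighbor words occurs (case-insensitive, whole-token) in the
same sentence; neighbor scope never crosses sentence boundaries. Genes with
an empty neighbor word set are unfilterable and pass by default
(`empty_set_policy="keep"`), since no gene should be silently unminable;
`"drop"` is available for precision-critical runs. The filter runs once,
upstream of both co-occurrence scopes, so sentence- and abstract-scope
results are computed from the same disambiguated occurrence table. It is
idempotent and per-gene independent.

## Sentence segmentation

A deterministic rule splitter: break at `.?!` followed by whitespace and a
capital letter or digit, unless the preceding token is a protected
abbreviation (e.g., i.e., et al., vs., Fig., ...). This is adequate for
abstract prose and keeps (doc, sentence-index) coordinates stable across
re-ingestion; the segmenter is a plug-in argument of `ingest_corpus` for
anyone needing another convention. Sentence-scope counts on real corpora
are necessarily segmenter-dependent.

## Dice scoring

Association strength is `2·f(x,y)/(f(x)+f(y))` with document frequencies
counted at abstract scope by default (sentence-scope frequencies behind a
flag). The coefficient is symmetric, lies in [0, 1], equals 1 exactly for
perfect overlap (f(x)=f(y)=f(x,y)>0), is strictly increasing in the joint
frequency at fixed marginals, and is 0 when the joint frequency is 0. A
product-denominator variant `2·f(x,y)/(f(x)·f(y))` is available behind
`denominator="product"` for auditing; it is not normalized (it reaches 2
for overlapping singletons) and never the default, because only the
sum-denominator form has the unit-interval perfect-overlap semantics the
heatmaps rely on.

## Pathway expansion

`expand_by_pathway` performs exactly one round: expanded = seeds ∪ {g : g
shares a pathway with a seed}, with full (pathway, seed) provenance per
added gene. Transitive closure is deliberately not applied — the seeds are
literature calls containing false positives, and closure would spread each
false seed through its entire pathway neighborhood and onward. Added genes
are reported separately from seeds so their lower evidence grade stays
visible.

## Validation

* **Curation CI**: the Wald interval `R ± z·sqrt(R(1−R)/n)`, z = 1.96,
  clamped to [0, 1], is the primary summary of a manual curation audit —
  chosen for its closed form and transparency at the audit sizes used
  (n ≈ 127), where it is accurate away from the boundaries. Its known
  defects (zero width at R ∈ {0, 1}, slight under-coverage) are documented
  by tests, and the Wilson score interval is available via
  `method="wilson"` for boundary-adjacent proportions.
* **Benchmark coverage**: |candidates ∩ benchmark| / |benchmark| over gene
  ids (never symbols — symbols are ambiguous).
* **Sampling**: uniform without replacement from the sorted gene list via
  a seeded NumPy generator; distinct seeds reproduce a repeated-audit
  design. The test suite verifies the per-gene inclusion frequency is
  uniform over 10,000 seeds.

## Heatmap overview

Rows (genes) and columns (terms) of the Dice matrix are clustered with
average linkage on Euclidean distance — mainstream heatmap defaults, both
configurable — and the matrix is rendered with the reordered grid exported
as TSV. Rendering is strictly side-effect: exported values equal input
values. All-zero gene rows are dropped from the display by default; they
carry no signal for the selected terms and would form a meaningless block.
Single-row or single-column matrices skip clustering trivially. Non-finite
scores are rejected rather than silently colored.

## Synthetic corpora: what they emulate, and what they do not

The generator emulates the structural features the pipeline's correctness
depends on: gene/term co-mentions at a controlled scope and document count,
symbols accompanied by neighbor words iff genuinely gene mentions,
English-word symbol collisions co-located with aging terms (the worst-case
false-positive generator), and filler/decoy documents. Symbols and neighbor
words are synthesized strings disjoint from all template text, so the
planted ground truth is *exact* and precision/recall can be scored to 1.0.

It does not emulate: natural language variability, abbreviation
definitions, casing noise, multi-gene sentences with entangled references,
or realistic term frequency distributions. Passing tests therefore certify
the pipeline's *mechanics* (matching, filtering, counting, scoring are
correct and internally consistent), not its real-corpus precision/recall,
which depends on dictionary quality and prose the generator does not model.
Corpus-scale gene counts from any particular MEDLINE snapshot are likewise
out of reach by design.

Default generation conditions: 50-document corpora with 3–6 sentences per
document, a 16-gene pool, 8 aging terms, 20% decoy documents in randomized
property-test specs, and 4–6 appearances per ambiguous symbol with the
decoy rate stated per experiment — small enough for fast exhaustive
oracles, large enough that scope containment and filtering effects are
non-trivial. The acceptance script uses 30 planted associations and 20
decoy documents in a 50-document corpus with an ambiguous symbol at decoy
rate 0.5.

## Numerical and degenerate-input choices

* Sentence indices are 0-based everywhere.
* Occurrence tables are deduplicated on (entity, doc, sentence) and carry a
  store content-hash; joining tables from different stores is an error.
* Greedy coverage-curve ordering breaks ties alphabetically; top-gene
  selection breaks ties by ascending gene id; both are therefore fully
  deterministic.
* `dice(0, 0, 0) = 0` by convention; a joint frequency exceeding a marginal
  is an invariant violation, not a clamp.
* Duplicate document ids at ingest: last record wins, with a warning;
  records without id or abstract are counted and skipped, never fatal.
* Empty aging-term files, empty benchmark sets, empty pathway member lists
  and empty seed sets are errors — each silently tolerated would produce a
  vacuously wrong downstream result.

## Known limitations

* The neighbor filter cannot validate symbols whose full names produce no
  informative words (empty word sets pass unfiltered by default).
* The disease general-word list is a shipped starting point, not a
  linguistic resource; corpus-specific tuning is expected.
* Wald intervals under-cover slightly near the boundaries; use Wilson
  when R approaches 0 or 1.
* One-round pathway expansion inherits whatever false positives the seed
  call contains; provenance makes them traceable but not absent.
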