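# Methods

## The ontology model

A PPI is modelled as an event with six facets — interactor (*who*),
biological process (*when*), subcellular location (*where*), interaction
type (*how*), biological function (*what*), detection method (*which*) —
each owning one root term. The term graph uses exactly three relationship
types: `is_a` (specialisation), `part_of` (temporal/spatial part–whole) and
`proper_part_of` (property–object); any other type is a validation error,
not a silent import. A term's facet is defined structurally as the facet of
the unique root it reaches over the union of the three edge types; terms
reaching zero or several roots are flagged. The `is_a` subgraph must be
acyclic, and we additionally require acyclicity of the combined graph — a
conservative reading of "hierarchy" that makes ancestor sets well-defined.
Roots are recognised in OBO input by their canonical names
(case-insensitive), so a file without those six names parses fine but is
treated as a generic source vocabulary: the root-reachability rule is then
simply not applicable (this is what lets a single sub-ontology fragment, or
a GO-like import source, validate on its own terms).

### OBO handling

Reader and writer target the OBO 1.2 flat dialect. Interpreted tags are
`id`, `name`, `def`, `synonym`, `is_a`, `relationship`, `is_obsolete` and
`xref` (the xref slot carries the source accession of imported terms —
provenance to the originating ontology). Any other tag is preserved
verbatim per term and re-emitted, giving lossless round-trips over real GO
/ PSI-MI exports without pretending to interpret trailing modifiers,
intersection tags, etc. Synonym scopes are read but deliberately collapsed:
for dictionary matching every synonym is an equally valid surface. The
writer is canonical — stanzas sorted by term id, tags in fixed order,
synonyms and edges sorted — so serialization is byte-deterministic and
`parse(write(x))` preserves terms, relationships and roots exactly.
Obsolete stanzas are retained and excluded from statistics and from the
dictionary.

## Construction

`import_terms` copies terms selected by an arbitrary predicate into a
target facet, keeping the source id as `source_ref`. The predicate is where
domain rules live; e.g. a cellular-component import that excludes
complex-named terms (a protein complex is a molecular machine, not a
location).

`filter_by_literature` applies one rule: a candidate whose primary name has
zero exact-match document hits is dropped — a term nobody writes cannot be
recognized in text. The counting itself is a pluggable provider; the
shipped implementation is a TSV-backed snapshot (term → count), which keeps
the pipeline offline and reproducible. Provider failures route the term to
an `unresolved` set rather than silently keeping it. Filtering on synonyms
as well would be a stricter variant; we filter on the primary name only,
since a term with a writable name but obscure synonyms is still usable.

### Interaction-type branch

The six top mechanism categories are fixed a priori (summarised from
molecular-interaction vocabularies): genetic interaction, physical
interaction, bio-chemical reaction, co-expression, co-localization, and an
unspecific bucket. Interaction-denoting words (verbs and nouns, deduplicated
on case-folded lemma + part of speech) are then organised bottom-up:

1. **Clustering.** Average-linkage agglomerative clustering on the
   dissimilarity 1 − sim, cut where merge similarity falls below
   `link_threshold` (default 0.5). Average linkage is deterministic and,
   because lemmas are sorted before the distance matrix is built, the
   partition is invariant to input order. scipy's implementation does the
   linkage; the semantic similarity is a pluggable provider (symmetric,
   self-similarity 1) — a pairwise-table provider for curated or
   precomputed similarities and a character-bigram Jaccard fallback for
   purely lexical runs. No WordNet-style resource is bundled.
2. **Attachment.** Each cluster attaches under the seeded category whose
   exemplar set has the highest mean similarity to the cluster's members;
   clusters scoring below `unspecific_floor` (default 0.25) against every
   seeded category fall into the unspecific bucket. With block-structured
   similarity (within 0.9, between 0.1) this recovers planted categories
   exactly, which is the regime the defaults are tuned for; real lexical
   similarities are noisier and the threshold is the knob to revisit.

Every input word ends up exactly once as a term with an `is_a` edge to its
category, and the emitted fragment always passes the validator.

## Dictionary and matching

Normalization is case-fold + whitespace collapse and nothing else: the
matching contract is case-insensitive string matching, and silently
stemming or stripping punctuation would change match semantics. A
last-token plural stemmer is available behind a flag (default off).
Surfaces shorter than 2 characters are dropped with a warning. A surface
owned by several terms maps to all of them; ambiguity is preserved into the
output rather than resolved by heuristic.

Matching scans the normalized sentence for every dictionary surface. The
normalization is position-preserving: each normalized character carries the
index of the original character that produced it, so reported spans always
index the raw text even when case-folding expands characters or whitespace
runs collapse. The word-boundary rule (on by default, configurable)
requires matches to be flanked by non-alphanumeric characters or string
edges — without it, `binding` fires inside `unbinding` and precision
collapses on real text.

**Longest-match resolution** is greedy and canonical: sort candidates by
(length descending, start ascending), accept a candidate iff it overlaps no
already-accepted match *of the same category*. Equal-length overlapping
ties therefore go to the left-most. Resolution is per category because the
facets are independent annotation axes: a location term nested inside a
longer process phrase should survive. A global-resolution mode is a flag. A
brute-force enumerator over all maximal non-overlapping subsets reproduces
the greedy answer on every random instance tested (the acceptance gate runs
1,000 of them).

**Assignment** is by sentence co-occurrence: every kept match is credited
to every PPI of the sentence, bucketed by the match's facet. When protein
mention spans are available, a match overlapping a PPI's own protein spans
is excluded for that PPI — interactors are participants, not context.
Sentence segmentation is out of scope; corpora arrive pre-segmented.

## Evaluation

The unit of comparison is the distinct (sentence_id, facet, normalized
surface) triple — the weakest assumption consistent with a gold list that
carries no character offsets — so a term credited to several PPIs of one
sentence counts once. A per-PPI scoring mode exists for the stricter
reading. TP/FP/FN are plain set intersections and differences per facet;
precision, recall and F follow, with every 0/0 mapped to 0 and flagged
`degenerate` instead of raising. The pooled `Total` row is the
micro-average (pool counts, then score); the macro-average is reported
alongside because the two diverge under facet imbalance. Scores are carried
at full precision internally, rounded to 3 decimals in JSON reports and 2
in the summary table.

## Synthetic fixtures

The generator emulates the *shape* of the real task — a six-branch ontology
and sentences each containing one or two PPIs plus planted term mentions —
under constructions chosen to make recovery exact rather than approximate:

- term surfaces are multi-word and end in a fixed-width unique token, so no
  surface is a substring of another;
- filler vocabulary and protein tokens (`PROTX####`) are disjoint from term
  tokens, so filler text can never contain a dictionary surface;
- planted surfaces are inserted at word boundaries, with occasional
  capitalisation to exercise case-insensitive matching;
- surfaces are drawn without replacement while the pool lasts, so at the
  scales used each planted mention has its own surface.

Hence an uncorrupted run must score exactly P = R = F = 1.000, and the
controlled degradations have clean expectations: dropping each planted
surface from the dictionary with probability q yields recall 1 − q
(per-mention binomial at these scales) with precision untouched, and
injecting never-planted dictionary surfaces into filler text at a chosen
per-sentence rate sets precision ≈ TP/(TP+FP) with recall untouched. The
corruption bookkeeping returns the exact realized TP/FP/FN, which the
evaluator must reproduce.

What passing these gates does **not** show: robustness to real biomedical
text — abbreviations, inflection, nested entity boundaries, imperfect
sentence segmentation, terms that are substrings of protein names — none of
which the generator produces. The fixtures verify the machinery, not the
linguistics.

Default study conditions: 500 sentences, 25 terms per facet, 2 planted
mentions per sentence in expectation; the degradation runs use 1,000
sentences and 200 terms per facet so that ≥ 2,000 planted mentions give the
binomial rates a standard error near 0.01. A single integer seed drives
ontology, corpus and corruption; fixed seed ⇒ byte-identical TSVs.

## Numerical and degenerate-input choices

- Overlap is on half-open intervals; zero-length spans cannot occur
  (surfaces are non-empty).
- Empty corpus, empty gold, all-zero confusion counts: all defined, never
  exceptions (degenerate metrics are flagged).
- An empty dictionary passed to the matcher is an error — it always
  indicates a wiring mistake, not a legitimate run.
- `fcluster` cut: merging while similarity ≥ t means cutting the dendrogram
  at distance 1 − t.
- Seeds handed to the acceptance script are reduced mod 2³¹ − 1 before use.

## Known limitations

- Dictionary matching is exact after normalization: no abbreviation
  expansion, no fuzzy matching, no morphological analysis beyond the
  optional plural stemmer.
- The shipped similarity providers are lexical; a semantic provider
  (distributional or lexicon-based) must be supplied by the caller for
  meaningful interaction-word clustering on real vocabularies.
- The literature filter's exact-match retrieval semantics live entirely in
  the count snapshot; the package only applies the zero-count rule.
- OWL export and reasoning beyond transitive closure are out of scope.
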