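# ppio — event-model ontology tooling for protein–protein interaction annotation

A protein–protein interaction (PPI) is not just an edge between two proteins:
it is a molecular event that happens somewhere, at some point of a biological
process, through some mechanism, with some functional effect, and is known
through some experimental evidence. `ppio` implements an event-centred
ontology schema for PPIs with six facets —

| facet | event role |
| --- | --- |
| interactor (role/state) | *who* |
| biological process | *when* |
| subcellular location | *where* |
| interaction type | *how* |
| biological function | *what* |
| detection method | *which* (the evidence) |

— together with the full tool chain around it:

- **`ppio.model`** — the ontology data model (terms, `is_a` / `part_of` /
  `proper_part_of` relationships, six category roots), a lossless OBO 1.2
  reader/writer with canonical serialization, a structural validator, term
  statistics and ancestor traversal.
- **`ppio.build`** — construction utilities: import terms from source
  vocabularies with provenance, remove candidates with zero exact-match
  literature hits (pluggable count provider), and build the interaction-type
  branch by average-linkage similarity clustering of interaction-denoting
  verbs/nouns under six fixed mechanism categories (genetic interaction,
  physical interaction, bio-chemical reaction, co-expression,
  co-localization, unspecific).
- **`ppio.dictionary`** — compile every term name and synonym into a
  normalized (case-folded, whitespace-collapsed) surface-form dictionary.
- **`ppio.extraction`** — dictionary matching over PPI-bearing sentences:
  find all case-insensitive occurrences at word boundaries, keep the longest
  of overlapping matches (`regulation of transcription` beats its nested
  `regulation`), and assign each kept term to every PPI co-occurring in the
  sentence, bucketed by facet.
- **`ppio.evaluation`** — score predictions against a curated gold corpus per
  facet and pooled, with precision = TP/(TP+FP), recall = TP/(TP+FN),
  F = 2PR/(P+R).
- **`ppio.synthetic`** — generators for toy six-branch ontologies and
  corpora with planted, known-truth annotations, plus controlled corruption
  (dictionary dropout → false negatives, distractor injection → false
  positives) for calibrating the evaluator.

## Worked example

Generate a 50-sentence synthetic corpus with planted annotations, annotate
it, and score it against its own gold standard:

```bash
ppio simulate --terms-per-cat 10 --sentences 50 --seed 7 --out demo
ppio annotate --obo demo/ontology.obo --sentences demo/sentences.tsv \
              --ppis demo/ppis.tsv --out demo/ann.tsv
ppio evaluate --pred demo/ann.tsv --gold demo/gold.tsv --out demo/report.tsv
```

```text
50 sentences, 62 PPIs, 100 gold tuples -> demo
62 annotated PPIs -> demo/ann.tsv
category	precision	recall	f_score
INTERACTOR	1.00	1.00	1.00
BIOLOGICAL_PROCESS	1.00	1.00	1.00
SUBCELLULAR_LOCATION	1.00	1.00	1.00
INTERACTION_TYPE	1.00	1.00	1.00
BIOLOGICAL_FUNCTION	1.00	1.00	1.00
DETECTION_METHOD	1.00	1.00	1.00
Total	1.00	1.00	1.00
Macro	1.00	1.00	1.00
```

An uncorrupted fixture must be recovered perfectly — the generator
guarantees that every planted surface is matchable and nothing else is, so
any score below 1.00 here would indicate a pipeline defect. Degrading the
dictionary shows the evaluator doing real work: with 30 % of planted
surfaces dropped from the dictionary, precision stays at 1.00 while recall
falls to the designed rate:

```bash
ppio simulate --terms-per-cat 50 --sentences 300 --seed 7 --dropout 0.3 --out degraded
ppio annotate --dictionary degraded/dictionary.tsv --sentences degraded/sentences.tsv \
              --ppis degraded/ppis.tsv --out degraded/ann.tsv
ppio evaluate --pred degraded/ann.tsv --gold degraded/gold.tsv --out degraded/report.tsv
```

```text
category	precision	recall	f_score
...
Total	1.00	0.72	0.84
```

The `Total` row pools TP/FP/FN over the six facets (micro-average); `Macro`
is the unweighted mean of the per-facet scores.

Other subcommands: `ppio validate` (structural report, exit 1 on
violations), `ppio compile` (dictionary TSV export), `ppio build-it`
(interaction-type branch from a word list + seed exemplars).

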