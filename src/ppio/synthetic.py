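"""Synthetic six-branch ontologies and corpora with planted ground truth.

The generator emulates the shape of the real inputs — a six-facet ontology
and a pre-segmented corpus of PPI-bearing sentences — under constructions
that make recovery *exact*: term surfaces are multi-word, mutually
non-substring, and disjoint from both the filler vocabulary and the protein
token family (``PROTX####``), so an uncorrupted end-to-end run must score
precision = recall = 1 and any deviation is a pipeline defect.  Controlled
degradation (dictionary dropout for false negatives, distractor injection
for false positives) then exercises the evaluator at known rates.

Everything is driven by one integer seed; a fixed seed reproduces the corpus
byte-for-byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .dictionary import TermDictionary
from .evaluation import ConfusionCounts, GoldAnnotation
from .extraction import PPIMention, Sentence
from .model import Category, Ontology, Relationship, Term

__all__ = ["PlantSpec", "gen_toy_ontology", "gen_corpus", "corrupt", "CorruptionResult"]

# Tokens used inside term names; disjoint from the filler vocabulary below.
_TERM_TOKENS = [
    "gamma", "delta", "flux", "axis", "node", "helix", "motif", "lattice",
    "vector", "matrix", "kernel", "cycle", "pulse", "cascade", "gradient",
    "domain", "sector", "orbit", "phase", "strand",
]

_FILLER_TOKENS = [
    "the", "observed", "under", "basal", "conditions", "while", "cells",
    "were", "treated", "and", "samples", "showed", "marked", "changes",
    "during", "incubation", "with", "control", "extracts", "over", "time",
    "notably", "in", "a", "dose", "dependent", "manner",
]

_VERB_PHRASES = [
    ("interacts", "with"),
    ("associates", "with"),
    ("binds", "to"),
]


@dataclass(frozen=True)
class PlantSpec:
    """Study conditions for one synthetic corpus."""

    n_sentences: int = 500
    terms_per_category: int = 25
    plants_per_sentence: float = 2.0
    dictionary_dropout_q: float = 0.0
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences <= 0 or self.terms_per_category <= 0:
            raise ValueError("n_sentences and terms_per_category must be positive")
        if not 0.0 <= self.dictionary_dropout_q < 1.0:
            raise ValueError("dictionary_dropout_q must lie in [0, 1)")
        if not 0.0 <= self.distractor_rate < 1.0:
            raise ValueError("distractor_rate must lie in [0, 1)")
        if self.plants_per_sentence < 0:
            raise ValueError("plants_per_sentence must be non-negative")


def gen_toy_ontology(terms_per_category: int, seed: int) -> Ontology:
    """Six-rooted toy ontology with multi-word, mutually non-substring names.

    Every name/synonym ends in a fixed-width unique token (``t00017``-style),
    which guarantees no surface is a substring of another.  Each term gets
    0-2 synonyms and attaches by ``is_a`` to the root or an earlier term of
    its branch (occasionally ``part_of``), giving the branches depth.
    """
    rng = random.Random(seed)
    onto = Ontology(header_lines=(f"format-version: 1.2", f"remark: toy ontology seed={seed}"))
    uid = 0
    for ci, cat in enumerate(Category, start=1):
        root_id = f"TOY:{ci:07d}"
        onto.add_term(Term(id=root_id, name=cat.label, category=cat))
        onto.roots[cat] = root_id
        branch_ids = [root_id]
        for k in range(terms_per_category):
            uid += 1
            w1, w2 = rng.choice(_TERM_TOKENS), rng.choice(_TERM_TOKENS)
            name = f"{w1} {w2} t{uid:05d}"
            synonyms = set()
            for j in range(rng.randint(0, 2)):
                synonyms.add(f"{rng.choice(_TERM_TOKENS)} alt s{uid:05d}x{j}")
            tid = f"TOY:{ci}{k + 1:06d}"
            onto.add_term(
                Term(id=tid, name=name, synonyms=synonyms, category=cat,
                     source_ref=f"SRC:{uid:07d}")
            )
            parent = rng.choice(branch_ids)
            rel_type = "part_of" if (parent != root_id and rng.random() < 0.15) else "is_a"
            onto.relationships.add(Relationship(tid, parent, rel_type))
            branch_ids.append(tid)
    return onto


def _poisson_like(rng: random.Random, rate: float) -> int:
    """floor(rate) plus a Bernoulli on the fractional part; mean = rate."""
    k = int(rate)
    if rng.random() < rate - k:
        k += 1
    return k


def _plant_pool(onto: Ontology) -> list[tuple[str, str, Category]]:
    """All (term_id, surface, category) triples of non-root, non-obsolete terms."""
    root_ids = set(onto.roots.values())
    pool = []
    for tid in sorted(onto.terms):
        term = onto.terms[tid]
        if tid in root_ids or term.is_obsolete or term.category is None:
            continue
        for surface in sorted(term.surfaces()):
            pool.append((tid, surface, term.category))
    return pool


def gen_corpus(
    onto: Ontology, spec: PlantSpec
) -> tuple[list[Sentence], list[PPIMention], list[GoldAnnotation]]:
    """Generate sentences with planted term mentions and gold annotations.

    Each sentence embeds one or two PPIs between reserved protein tokens and
    0+ planted term surfaces at word boundaries; the gold list records
    exactly the planted (sentence_id, category, surface) triples.  Surfaces
    are drawn without replacement while the pool lasts, so at corpus scale
    each planted mention tends to carry its own surface.
    """
    rng = random.Random(spec.seed)
    pool = _plant_pool(onto)
    rng.shuffle(pool)
    cursor = 0

    def next_plant():
        nonlocal cursor, pool
        if cursor >= len(pool):
            pool = pool[:]
            rng.shuffle(pool)
            cursor = 0
        item = pool[cursor]
        cursor += 1
        return item

    sentences: list[Sentence] = []
    ppis: list[PPIMention] = []
    gold: set[GoldAnnotation] = set()
    protein_counter = 0

    for si in range(spec.n_sentences):
        sid = f"S{si + 1:05d}"
        n_ppis = 1 + (1 if rng.random() < 0.3 else 0)
        n_plants = _poisson_like(rng, spec.plants_per_sentence)

        # Token stream with markers for spans.
        tokens: list[tuple[str, str | None]] = []  # (token text, marker)
        ppi_specs = []
        for p in range(n_ppis):
            protein_counter += 1
            pa = f"PROTX{protein_counter:04d}"
            protein_counter += 1
            pb = f"PROTX{protein_counter:04d}"
            verb = rng.choice(_VERB_PHRASES)
            ppi_specs.append((pa, pb))
            if p > 0:
                tokens.append((rng.choice(["moreover", "additionally"]), None))
            tokens.append((pa, f"prot:{pa}"))
            tokens.extend((v, None) for v in verb)
            tokens.append((pb, f"prot:{pb}"))
            tokens.extend(
                (rng.choice(_FILLER_TOKENS), None) for _ in range(rng.randint(1, 4))
            )

        planted_here: set[str] = set()
        plants = []
        for _ in range(n_plants):
            for _attempt in range(10):
                tid, surface, cat = next_plant()
                if surface not in planted_here:
                    break
            else:
                continue
            planted_here.add(surface)
            plants.append((tid, surface, cat))

        for tid, surface, cat in plants:
            # Random display casing exercises case-insensitive matching.
            display = surface.capitalize() if rng.random() < 0.3 else surface
            insert_at = rng.randint(0, len(tokens))
            tokens[insert_at:insert_at] = [(display, None)]
            tokens.extend((rng.choice(_FILLER_TOKENS), None) for _ in range(rng.randint(0, 2)))
            gold.add(GoldAnnotation.make(sid, cat, surface))

        tokens.append((".", None))

        # Assemble text and protein spans.
        text_parts: list[str] = []
        spans: dict[str, tuple[int, int]] = {}
        pos = 0
        for tok, marker in tokens:
            if text_parts:
                pos += 1  # joining space
            start = pos
            text_parts.append(tok)
            pos += len(tok)
            if marker is not None:
                spans[marker] = (start, pos)
        text = " ".join(text_parts)

        sentences.append(Sentence(sid, text))
        for pa, pb in ppi_specs:
            ppis.append(
                PPIMention(sid, pa, pb, span_a=spans[f"prot:{pa}"], span_b=spans[f"prot:{pb}"])
            )

    gold_sorted = sorted(gold, key=lambda g: (g.sentence_id, g.category.name, g.term_surface))
    return sentences, ppis, gold_sorted


@dataclass
class CorruptionResult:
    sentences: list[Sentence]
    dictionary: TermDictionary
    gold: list[GoldAnnotation]
    expected: ConfusionCounts
    dropped_surfaces: set[str] = field(default_factory=set)
    injected: list[tuple[str, str]] = field(default_factory=list)  # (sentence_id, surface)


def corrupt(
    sentences: list[Sentence],
    dictionary: TermDictionary,
    gold: list[GoldAnnotation],
    spec: PlantSpec,
) -> CorruptionResult:
    """Degrade a planted corpus at controlled false-negative/-positive rates.

    ``dictionary_dropout_q`` removes each *planted* surface from the
    dictionary independently with probability q — its mentions become false
    negatives.  ``distractor_rate`` injects, per sentence with that
    probability, one never-planted dictionary surface into the filler text —
    a false positive, since the gold list is left untouched.  The returned
    bookkeeping gives the exact tp/fp/fn an evaluation must realize.
    """
    rng = random.Random(spec.seed + 7919)
    planted_surfaces = sorted({g.term_surface for g in gold})

    dropped = {s for s in planted_surfaces if rng.random() < spec.dictionary_dropout_q}
    new_dict = TermDictionary(
        entries={k: v for k, v in dictionary.entries.items() if k not in dropped},
        provenance=dictionary.provenance,
        stemmed=dictionary.stemmed,
    )

    distractor_pool = sorted(set(new_dict.entries) - set(planted_surfaces))
    rng.shuffle(distractor_pool)
    cursor = 0
    injected: list[tuple[str, str]] = []
    new_sentences: list[Sentence] = []
    for sent in sentences:
        if spec.distractor_rate > 0 and distractor_pool and rng.random() < spec.distractor_rate:
            surface = distractor_pool[cursor % len(distractor_pool)]
            cursor += 1
            body = sent.text[:-2] if sent.text.endswith(" .") else sent.text
            tail = " ." if sent.text.endswith(" .") else ""
            new_sentences.append(Sentence(sent.sentence_id, f"{body} {surface}{tail}"))
            injected.append((sent.sentence_id, surface))
        else:
            new_sentences.append(sent)

    fn = sum(1 for g in gold if g.term_surface in dropped)
    tp = len(gold) - fn
    fp = len({(sid, s) for sid, s in injected})
    return CorruptionResult(
        sentences=new_sentences,
        dictionary=new_dict,
        gold=list(gold),
        expected=ConfusionCounts(tp=tp, fp=fp, fn=fn),
        dropped_surfaces=dropped,
        injected=injected,
    )
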