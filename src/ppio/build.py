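"""Ontology construction utilities.

Terms are imported from existing source vocabularies with their original
accession kept as provenance; candidates with zero exact-match literature
hits are removed (a term nobody writes cannot be recognized in text); and the
interaction-type branch is built by fixing six top-level mechanism
categories (genetic interaction, physical interaction, bio-chemical
reaction, co-expression, co-localization, unspecific) and clustering
interaction-denoting verbs/nouns bottom-up by semantic similarity.

Literature counting and word similarity are pluggable contracts so the
pipeline runs offline: a count provider maps a term surface to a document
count; a similarity provider maps a lemma pair to a score in [0, 1].
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import Category, Ontology, Relationship, Term

__all__ = [
    "InteractionWord",
    "TsvLiteratureCounts",
    "MatrixSimilarity",
    "BigramJaccardSimilarity",
    "LiteratureFilterResult",
    "import_terms",
    "filter_by_literature",
    "dedupe_words",
    "build_interaction_type_subontology",
    "INTERACTION_TYPE_TOP_CATEGORIES",
    "read_words_tsv",
]

# Fixed top level of the interaction-type branch; "unspecific" is the
# fallback bucket for words no seeded category claims.
INTERACTION_TYPE_TOP_CATEGORIES = (
    "genetic interaction",
    "physical interaction",
    "bio-chemical reaction",
    "co-expression",
    "co-localization",
    "unspecific",
)
UNSPECIFIC = "unspecific"


@dataclass(frozen=True)
class InteractionWord:
    """A verb or noun denoting a protein interaction."""

    lemma: str
    pos: str  # "verb" | "noun"
    assigned_category: str | None = None

    def __post_init__(self):
        if not self.lemma or self.lemma != self.lemma.lower():
            raise ValueError(f"lemma must be lowercase and non-empty: {self.lemma!r}")
        if self.pos not in ("verb", "noun"):
            raise ValueError(f"pos must be 'verb' or 'noun': {self.pos!r}")


# ---------------------------------------------------------------------------
# Pluggable providers
# ---------------------------------------------------------------------------

LiteratureCountProvider = Callable[[str], int]
SimilarityProvider = Callable[[str, str], float]


class TsvLiteratureCounts:
    """File-backed count provider (TSV columns: term, count).

    Stands in for an online exact-match retrieval snapshot; deterministic by
    construction.  Unknown terms raise ``KeyError``.
    """

    def __init__(self, counts: Mapping[str, int]):
        self._counts = {k: int(v) for k, v in counts.items()}

    @classmethod
    def from_tsv(cls, path) -> "TsvLiteratureCounts":
        counts = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                counts[row["term"]] = int(row["count"])
        return cls(counts)

    def __call__(self, term_surface: str) -> int:
        n = self._counts[term_surface]
        if n < 0:
            raise ValueError(f"negative count for {term_surface!r}")
        return n


class MatrixSimilarity:
    """Similarity provider backed by an explicit pairwise table.

    Unlisted pairs fall back to ``default``; symmetry and sim(w, w) = 1 are
    enforced by construction.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float], default: float = 0.0):
        self._pairs: dict[frozenset, float] = {}
        for (a, b), s in pairs.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"similarity out of [0,1]: {s}")
            self._pairs[frozenset((a, b))] = float(s)
        self.default = default

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), self.default)


class BigramJaccardSimilarity:
    """Character-bigram Jaccard similarity — a lightweight lexical fallback
    when no semantic similarity resource is configured."""

    @staticmethod
    def _bigrams(w: str) -> set[str]:
        padded = f"^{w}$"
        return {padded[i : i + 2] for i in range(len(padded) - 1)}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ba, bb = self._bigrams(a), self._bigrams(b)
        union = ba | bb
        return len(ba & bb) / len(union) if union else 1.0


# ---------------------------------------------------------------------------
# Term import and literature filtering
# ---------------------------------------------------------------------------


def import_terms(
    source: Ontology,
    selector: Callable[[Term], bool],
    target_category: Category,
    id_prefix: str | None = None,
) -> set[Term]:
    """Copy the selected source terms into the target facet with provenance.

    Each returned term keeps its original accession as ``source_ref``.  When
    ``id_prefix`` is given, ids are re-minted as ``prefix:NNNNNNN`` (sorted by
    source id) to avoid collisions when merging several sources.
    """
    selected = [source.terms[tid] for tid in sorted(source.terms) if selector(source.terms[tid])]
    if not selected:
        warnings.warn("selector matched no source terms", stacklevel=2)
        return set()
    out = set()
    for i, src in enumerate(selected, start=1):
        new_id = f"{id_prefix}:{i:07d}" if id_prefix else src.id
        out.add(
            Term(
                id=new_id,
                name=src.name,
                synonyms=set(src.synonyms),
                definition=src.definition,
                source_ref=src.id,
                category=target_category,
                is_obsolete=src.is_obsolete,
            )
        )
    return out


class LiteratureFilterResult(NamedTuple):
    kept: set[Term]
    dropped: set[Term]
    unresolved: set[Term]


def filter_by_literature(
    terms: Iterable[Term], provider: LiteratureCountProvider
) -> LiteratureFilterResult:
    """Remove candidate terms with zero exact-match literature hits.

    The zero-count rule is applied to the primary name (``filter_synonyms``
    semantics belong to the provider snapshot, not here).  Terms the provider
    cannot resolve are routed to ``unresolved`` — never silently kept.
    """
    kept, dropped, unresolved = set(), set(), set()
    for term in terms:
        try:
            count = provider(term.name)
        except Exception:
            unresolved.add(term)
            continue
        (dropped if count == 0 else kept).add(term)
    return LiteratureFilterResult(kept, dropped, unresolved)


def dedupe_words(words: list[InteractionWord]) -> list[InteractionWord]:
    """Drop redundant words: unique on case-folded (lemma, pos), keeping the
    first occurrence in stable order."""
    seen: set[tuple[str, str]] = set()
    out = []
    for w in words:
        key = (w.lemma.casefold(), w.pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(w)
    return out


def read_words_tsv(path) -> list[InteractionWord]:
    """Columns: lemma, pos."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(InteractionWord(lemma=row["lemma"].strip().lower(), pos=row["pos"].strip().lower()))
    return out


# ---------------------------------------------------------------------------
# Interaction-type sub-ontology
# ---------------------------------------------------------------------------


def _cluster_words(
    lemmas: list[str], sim: SimilarityProvider, link_threshold: float
) -> list[list[str]]:
    """Average-linkage agglomerative clustering cut at the similarity
    threshold.  Lemmas are sorted first so the partition is independent of
    input order."""
    lemmas = sorted(lemmas)
    if len(lemmas) == 1:
        return [lemmas]
    n = len(lemmas)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = float(sim(lemmas[i], lemmas[j]))
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"similarity out of [0,1] for ({lemmas[i]}, {lemmas[j]}): {s}")
            d[i, j] = d[j, i] = 1.0 - s
    z = linkage(squareform(d, checks=False), method="average")
    # Merging while similarity >= threshold means cutting at distance
    # 1 - threshold.
    labels = fcluster(z, t=1.0 - link_threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lemma, lab in zip(lemmas, labels):
        clusters.setdefault(int(lab), []).append(lemma)
    return [clusters[k] for k in sorted(clusters, key=lambda k: clusters[k][0])]


def build_interaction_type_subontology(
    words: list[InteractionWord],
    seeds: Mapping[str, Iterable[str]],
    sim: SimilarityProvider,
    link_threshold: float = 0.5,
    unspecific_floor: float = 0.25,
    id_prefix: str = "PPIO:IT",
) -> Ontology:
    """Build the interaction-type branch: six fixed mechanism categories on
    top, similarity clusters of interaction words below.

    Words are clustered by average-linkage under ``sim`` and each cluster is
    attached beneath the seeded category whose exemplars are most similar on
    average; clusters below ``unspecific_floor`` against every seeded
    category fall into the unspecific bucket.  Every input word appears
    exactly once, as a term with an ``is_a`` edge to its category.
    """
    if not 0.0 <= link_threshold <= 1.0:
        raise ValueError(f"link_threshold must lie in [0,1]: {link_threshold}")
    unknown = set(seeds) - set(INTERACTION_TYPE_TOP_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown seed categories: {sorted(unknown)}")

    onto = Ontology()
    root_id = f"{id_prefix}:0000000"
    onto.add_term(Term(id=root_id, name=Category.INTERACTION_TYPE.label,
                       category=Category.INTERACTION_TYPE))
    onto.roots[Category.INTERACTION_TYPE] = root_id
    cat_ids: dict[str, str] = {}
    for i, cat_name in enumerate(INTERACTION_TYPE_TOP_CATEGORIES, start=1):
        cid = f"{id_prefix}:{i:07d}"
        cat_ids[cat_name] = cid
        onto.add_term(Term(id=cid, name=cat_name, category=Category.INTERACTION_TYPE))
        onto.relationships.add(Relationship(cid, root_id, "is_a"))

    words = dedupe_words(list(words))
    if not words:
        return onto

    by_lemma: dict[str, list[InteractionWord]] = {}
    for w in words:
        by_lemma.setdefault(w.lemma, []).append(w)
    clusters = _cluster_words(sorted(by_lemma), sim, link_threshold)

    seeded = {c: sorted(set(ex)) for c, ex in seeds.items() if list(ex) and c != UNSPECIFIC}
    assignment: dict[str, str] = {}
    for cluster in clusters:
        best_cat, best_score = UNSPECIFIC, -1.0
        for cat_name in INTERACTION_TYPE_TOP_CATEGORIES:
            exemplars = seeded.get(cat_name)
            if not exemplars:
                continue
            score = float(
                np.mean([sim(lemma, ex) for lemma in cluster for ex in exemplars])
            )
            if score > best_score:
                best_cat, best_score = cat_name, score
        if best_score < unspecific_floor:
            best_cat = UNSPECIFIC
        for lemma in cluster:
            assignment[lemma] = best_cat

    next_idx = len(INTERACTION_TYPE_TOP_CATEGORIES) + 1
    for lemma in sorted(by_lemma):
        cat_name = assignment[lemma]
        tid = f"{id_prefix}:{next_idx:07d}"
        next_idx += 1
        poses = {w.pos for w in by_lemma[lemma]}
        onto.add_term(
            Term(
                id=tid,
                name=lemma,
                definition=f"interaction word ({'/'.join(sorted(poses))})",
                category=Category.INTERACTION_TYPE,
            )
        )
        onto.relationships.add(Relationship(tid, cat_ids[cat_name], "is_a"))
    return onto


def assign_words(
    words: list[InteractionWord], fragment: Ontology
) -> list[InteractionWord]:
    """Return the words with ``assigned_category`` filled from a built
    fragment (lemma-name lookup)."""
    cat_of: dict[str, str] = {}
    parents = {r.child: r.parent for r in fragment.relationships}
    names = {tid: t.name for tid, t in fragment.terms.items()}
    for tid, t in fragment.terms.items():
        if t.name in {w.lemma for w in words} and tid in parents:
            cat_of[t.name] = names[parents[tid]]
    return [replace(w, assigned_category=cat_of.get(w.lemma)) for w in words]
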