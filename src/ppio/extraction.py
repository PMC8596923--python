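"""Dictionary matching over PPI-bearing sentences.

The pipeline is three steps per sentence: (1) find every occurrence of every
dictionary surface, case-insensitively and (by default) at word boundaries;
(2) resolve overlapping matches by keeping the longest (e.g. ``regulation of
transcription`` wins over its nested ``regulation``); (3) assign each kept
match to every PPI of the sentence — co-occurrence of a term and a PPI in one
sentence is the annotation signal.

Spans always index the *original* sentence text; normalization is performed
through a position-preserving fold so that case-folding and whitespace
collapsing never desynchronise offsets.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

from .dictionary import TermDictionary, light_stem
from .model import Category

__all__ = [
    "Sentence",
    "PPIMention",
    "Match",
    "AnnotatedPPI",
    "normalize_with_offsets",
    "find_matches",
    "resolve_longest",
    "assign_annotations",
    "annotate_corpus",
]


@dataclass(frozen=True)
class Sentence:
    sentence_id: str
    text: str

    def __post_init__(self):
        if not self.text:
            raise ValueError("sentence text must be non-empty")


@dataclass(frozen=True)
class PPIMention:
    """A protein pair asserted to interact within one sentence.

    Spans are 0-based half-open character intervals into the sentence text;
    they are optional (the gold corpus format may omit them).
    """

    sentence_id: str
    protein_a: str
    protein_b: str
    span_a: tuple[int, int] | None = None
    span_b: tuple[int, int] | None = None


@dataclass(frozen=True)
class Match:
    """One recognized term occurrence: a span, its surface, and the owning
    terms of one category (ambiguous surfaces yield one Match per category)."""

    span: tuple[int, int]
    surface: str
    term_ids: frozenset[str]
    category: Category

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def overlaps(self, other: "Match") -> bool:
        return self.span[0] < other.span[1] and other.span[0] < self.span[1]


@dataclass
class AnnotatedPPI:
    ppi: PPIMention
    annotations: dict[Category, set[tuple[str, str]]] = field(default_factory=dict)

    def all_tuples(self) -> set[tuple[str, Category, str]]:
        """(sentence_id, category, surface) triples carried by this PPI."""
        out = set()
        for cat, pairs in self.annotations.items():
            for _tid, surface in pairs:
                out.add((self.ppi.sentence_id, cat, surface))
        return out


def normalize_with_offsets(text: str) -> tuple[str, list[int]]:
    """Case-fold and collapse whitespace, keeping a norm->original offset map.

    Returns ``(norm, offsets)`` with ``offsets[i]`` the index in ``text`` of
    the character that produced ``norm[i]``.  Whitespace runs collapse to one
    space mapped to the run's first character; leading/trailing whitespace is
    dropped.
    """
    norm_chars: list[str] = []
    offsets: list[int] = []
    pending_ws: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if pending_ws is None:
                pending_ws = i
            continue
        if pending_ws is not None and norm_chars:
            norm_chars.append(" ")
            offsets.append(pending_ws)
        pending_ws = None
        for fc in ch.casefold():
            norm_chars.append(fc)
            offsets.append(i)
    return "".join(norm_chars), offsets


def _is_boundary(norm: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not norm[start - 1].isalnum()
    after_ok = end == len(norm) or not norm[end].isalnum()
    return before_ok and after_ok


def _matches_for_surface(norm: str, surface: str, boundaries: bool) -> list[tuple[int, int]]:
    spans = []
    start = 0
    while True:
        idx = norm.find(surface, start)
        if idx == -1:
            break
        end = idx + len(surface)
        if not boundaries or _is_boundary(norm, idx, end):
            spans.append((idx, end))
        start = idx + 1
    return spans


def _orig_span(offsets: list[int], start: int, end: int) -> tuple[int, int]:
    return offsets[start], offsets[end - 1] + 1


def find_matches(
    sent: Sentence, dictionary: TermDictionary, boundaries: bool = True
) -> list[Match]:
    """Report every dictionary surface occurrence in the sentence.

    Matching is case-insensitive over the normalized text; the word-boundary
    rule (default on) requires each occurrence to be flanked by non-alphanumeric
    characters or string edges, so ``binding`` does not fire inside
    ``unbinding``.  Overlapping and nested occurrences are all reported;
    resolution is a separate step.
    """
    if not dictionary.entries:
        raise ValueError("dictionary is empty")
    norm, offsets = normalize_with_offsets(sent.text)
    matches: list[Match] = []
    if dictionary.stemmed:
        matches.extend(_find_matches_stemmed(sent, norm, offsets, dictionary, boundaries))
        return matches
    for surface in sorted(dictionary.entries):
        entry = dictionary.entries[surface]
        for nstart, nend in _matches_for_surface(norm, surface, boundaries):
            span = _orig_span(offsets, nstart, nend)
            by_cat: dict[Category, set[str]] = {}
            for tid in entry.term_ids:
                cat = entry.category_per_term.get(tid)
                if cat is not None:
                    by_cat.setdefault(cat, set()).add(tid)
            for cat, tids in sorted(by_cat.items(), key=lambda kv: kv[0].name):
                matches.append(Match(span, surface, frozenset(tids), cat))
    return matches


def _find_matches_stemmed(sent, norm, offsets, dictionary, boundaries):
    """Plural-insensitive mode: match token n-grams under last-token stemming."""
    # Token spans over the normalized text (whitespace-delimited).
    tokens: list[tuple[int, int]] = []
    i = 0
    while i < len(norm):
        if norm[i] == " ":
            i += 1
            continue
        j = i
        while j < len(norm) and norm[j] != " ":
            j += 1
        tokens.append((i, j))
        i = j
    max_n = max((s.count(" ") + 1 for s in dictionary.entries), default=1)
    out = []
    for a in range(len(tokens)):
        for n in range(1, min(max_n, len(tokens) - a) + 1):
            nstart, nend = tokens[a][0], tokens[a + n - 1][1]
            # Trim flanking punctuation inside the token window.
            while nstart < nend and not norm[nstart].isalnum():
                nstart += 1
            while nend > nstart and not norm[nend - 1].isalnum():
                nend -= 1
            if nend <= nstart:
                continue
            candidate = norm[nstart:nend]
            toks = candidate.split()
            toks[-1] = light_stem(toks[-1])
            key = " ".join(toks)
            entry = dictionary.entries.get(key)
            if entry is None:
                continue
            if boundaries and not _is_boundary(norm, nstart, nend):
                continue
            span = _orig_span(offsets, nstart, nend)
            by_cat: dict[Category, set[str]] = {}
            for tid in entry.term_ids:
                cat = entry.category_per_term.get(tid)
                if cat is not None:
                    by_cat.setdefault(cat, set()).add(tid)
            for cat, tids in sorted(by_cat.items(), key=lambda kv: kv[0].name):
                out.append(Match(span, key, frozenset(tids), cat))
    return out


def resolve_longest(matches: list[Match], per_category: bool = True) -> list[Match]:
    """Keep the longest of overlapping matches (greedy, deterministic).

    Matches are sorted by (length descending, start ascending) and accepted
    iff they overlap no already-accepted match of the same category (or of any
    category when ``per_category=False``).  Equal-length overlapping matches
    therefore resolve to the left-most.  Categories are independent annotation
    axes, so a location term nested inside a longer process phrase survives by
    default.
    """
    order = sorted(matches, key=lambda m: (-m.length, m.span[0], m.category.name, m.surface))
    kept: list[Match] = []
    for cand in order:
        blocked = any(
            cand.overlaps(acc)
            and (not per_category or acc.category == cand.category)
            for acc in kept
        )
        if not blocked:
            kept.append(cand)
    kept.sort(key=lambda m: (m.span, m.category.name, m.surface))
    return kept


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assign_annotations(
    sent: Sentence,
    ppis: list[PPIMention],
    kept: list[Match],
    exclude_protein_overlap: bool = True,
) -> list[AnnotatedPPI]:
    """Bucket every kept match onto every PPI of the sentence, per category.

    A match whose span overlaps one of a PPI's protein-mention spans (when
    spans are provided) is excluded from that PPI's annotations: protein
    names are the interactors themselves, not context terms.
    """
    for ppi in ppis:
        if ppi.sentence_id != sent.sentence_id:
            raise ValueError(
                f"PPI sentence_id {ppi.sentence_id!r} does not match sentence {sent.sentence_id!r}"
            )
    out = []
    for ppi in ppis:
        ann: dict[Category, set[tuple[str, str]]] = {cat: set() for cat in Category}
        for m in kept:
            if exclude_protein_overlap:
                protein_spans = [s for s in (ppi.span_a, ppi.span_b) if s is not None]
                if any(_spans_overlap(m.span, ps) for ps in protein_spans):
                    continue
            for tid in m.term_ids:
                ann[m.category].add((tid, m.surface))
        out.append(AnnotatedPPI(ppi=ppi, annotations=ann))
    return out


def annotate_corpus(
    sentences: list[Sentence],
    ppis: list[PPIMention],
    dictionary: TermDictionary,
    boundaries: bool = True,
    per_category: bool = True,
    exclude_protein_overlap: bool = True,
    log=None,
) -> list[AnnotatedPPI]:
    """Run find -> resolve -> assign over a whole pre-segmented corpus.

    Sentences without a PPI contribute nothing (there is no edge to
    annotate).  Output order follows sentence order, then PPI order.
    """
    ppis_by_sent: dict[str, list[PPIMention]] = {}
    for ppi in ppis:
        ppis_by_sent.setdefault(ppi.sentence_id, []).append(ppi)
    out: list[AnnotatedPPI] = []
    for sent in sentences:
        sent_ppis = ppis_by_sent.get(sent.sentence_id, [])
        if not sent_ppis:
            continue
        matches = find_matches(sent, dictionary, boundaries=boundaries)
        kept = resolve_longest(matches, per_category=per_category)
        if log is not None:
            log(f"{sent.sentence_id}: {len(matches)} matches, {len(kept)} kept")
        out.extend(
            assign_annotations(
                sent, sent_ppis, kept, exclude_protein_overlap=exclude_protein_overlap
            )
        )
    return out


# ---------------------------------------------------------------------------
# Corpus and annotation TSV/JSON dialects
# ---------------------------------------------------------------------------


def read_sentences_tsv(path) -> list[Sentence]:
    """Columns: sentence_id, text."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(Sentence(row["sentence_id"], row["text"]))
    return out


def read_ppis_tsv(path) -> list[PPIMention]:
    """Columns: sentence_id, protein_a, protein_b and optional span columns."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            def span(prefix):
                s, e = row.get(f"{prefix}_start", ""), row.get(f"{prefix}_end", "")
                return (int(s), int(e)) if s not in ("", None) and e not in ("", None) else None

            out.append(
                PPIMention(
                    sentence_id=row["sentence_id"],
                    protein_a=row["protein_a"],
                    protein_b=row["protein_b"],
                    span_a=span("span_a"),
                    span_b=span("span_b"),
                )
            )
    return out


def write_sentences_tsv(sentences: list[Sentence], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sentence_id", "text"])
        for s in sentences:
            w.writerow([s.sentence_id, s.text])


def write_ppis_tsv(ppis: list[PPIMention], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sentence_id", "protein_a", "protein_b",
             "span_a_start", "span_a_end", "span_b_start", "span_b_end"]
        )
        for p in ppis:
            a = p.span_a or ("", "")
            b = p.span_b or ("", "")
            w.writerow([p.sentence_id, p.protein_a, p.protein_b, a[0], a[1], b[0], b[1]])


def write_annotations_tsv(annotated: list[AnnotatedPPI], path, header_lines: list[str] = ()) -> None:
    """One row per assigned term; columns mirror the annotation record."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sentence_id", "protein_a", "protein_b", "category", "term_id", "surface"]
        )
        for ap in annotated:
            for cat in Category:
                for tid, surface in sorted(ap.annotations.get(cat, ())):
                    w.writerow(
                        [ap.ppi.sentence_id, ap.ppi.protein_a, ap.ppi.protein_b,
                         cat.name, tid, surface]
                    )


def read_annotations_tsv(path) -> list[AnnotatedPPI]:
    by_ppi: dict[tuple, AnnotatedPPI] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        key = (row["sentence_id"], row["protein_a"], row["protein_b"])
        if key not in by_ppi:
            ppi = PPIMention(row["sentence_id"], row["protein_a"], row["protein_b"])
            by_ppi[key] = AnnotatedPPI(ppi=ppi, annotations={c: set() for c in Category})
        cat = Category.from_name(row["category"])
        by_ppi[key].annotations[cat].add((row["term_id"], row["surface"]))
    return list(by_ppi.values())


def annotations_to_json(annotated: list[AnnotatedPPI]) -> str:
    payload = []
    for ap in annotated:
        payload.append(
            {
                "sentence_id": ap.ppi.sentence_id,
                "protein_a": ap.ppi.protein_a,
                "protein_b": ap.ppi.protein_b,
                "annotations": {
                    cat.name: sorted([tid, surface] for tid, surface in pairs)
                    for cat, pairs in ap.annotations.items()
                    if pairs
                },
            }
        )
    return json.dumps(payload, indent=2) + "\n"
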