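"""Compile ontology terms into a normalized surface-form dictionary.

Every name and synonym of every non-obsolete term becomes a lookup key after
normalization (case-fold, whitespace collapse).  A surface owned by several
terms keeps all of them — ambiguity is preserved for downstream review, not
resolved here.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .model import Category, Ontology

__all__ = [
    "SurfaceEntry",
    "TermDictionary",
    "normalize_surface",
    "compile_dictionary",
]

MIN_SURFACE_LEN = 2


def normalize_surface(s: str) -> str:
    """Case-fold, trim, and collapse internal whitespace runs to one space."""
    return " ".join(s.casefold().split())


def light_stem(word: str) -> str:
    """Strip a plural suffix from one token (optional matching mode)."""
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    for suf in ("sses", "xes", "zes", "ches", "shes"):
        if word.endswith(suf) and len(word) > len(suf) + 1:
            return word[:-2]
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    return word


def stem_surface(s: str) -> str:
    """Normalize then stem the final token (plural-insensitive key)."""
    toks = normalize_surface(s).split()
    if toks:
        toks[-1] = light_stem(toks[-1])
    return " ".join(toks)


@dataclass
class SurfaceEntry:
    surface: str
    term_ids: set[str] = field(default_factory=set)
    category_per_term: dict[str, Category] = field(default_factory=dict)


@dataclass
class TermDictionary:
    """Normalized surface form -> owning terms."""

    entries: dict[str, SurfaceEntry] = field(default_factory=dict)
    provenance: str = ""
    stemmed: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return surface in self.entries

    def key_for(self, raw: str) -> str:
        return stem_surface(raw) if self.stemmed else normalize_surface(raw)

    def lookup(self, raw: str) -> SurfaceEntry | None:
        return self.entries.get(self.key_for(raw))

    def remove_surface(self, surface: str) -> bool:
        """Drop one surface key (used by controlled-degradation fixtures)."""
        return self.entries.pop(self.key_for(surface), None) is not None

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["surface", "term_id", "category"])
            for surface in sorted(self.entries):
                entry = self.entries[surface]
                for tid in sorted(entry.term_ids):
                    cat = entry.category_per_term.get(tid)
                    w.writerow([surface, tid, cat.name if cat else ""])

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "TermDictionary":
        d = cls(provenance=provenance)
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                surface = row["surface"]
                entry = d.entries.setdefault(surface, SurfaceEntry(surface=surface))
                entry.term_ids.add(row["term_id"])
                if row.get("category"):
                    entry.category_per_term[row["term_id"]] = Category.from_name(row["category"])
        return d


def compile_dictionary(
    onto: Ontology,
    categories: Iterable[Category] | None = None,
    stemming: bool = False,
    min_surface_len: int = MIN_SURFACE_LEN,
) -> TermDictionary:
    """Build the matching dictionary from every selected non-obsolete term.

    Parameters
    ----------
    categories
        Facets to include; ``None`` means all six.  An explicitly empty
        selection is a parameter error.
    stemming
        When true, keys are additionally plural-stemmed on the last token.
    min_surface_len
        Surfaces shorter than this (after normalization) are dropped with a
        warning; guards against pathological single-character matches.
    """
    if categories is None:
        cats = set(Category)
    else:
        cats = set(categories)
        if not cats:
            raise ValueError("empty category selection")
    d = TermDictionary(provenance=onto.header_lines[0] if onto.header_lines else "", stemmed=stemming)
    normalize = stem_surface if stemming else normalize_surface
    for tid in sorted(onto.terms):
        term = onto.terms[tid]
        if term.is_obsolete or term.category not in cats:
            continue
        for raw in sorted(term.surfaces()):
            surface = normalize(raw)
            if not surface:
                continue
            if len(surface) < min_surface_len:
                warnings.warn(f"dropping too-short surface {raw!r} of term {tid}", stacklevel=2)
                continue
            entry = d.entries.setdefault(surface, SurfaceEntry(surface=surface))
            entry.term_ids.add(tid)
            entry.category_per_term[tid] = term.category
    return d
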