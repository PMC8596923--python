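"""Independent brute-force oracles shared across test modules.

These deliberately re-derive expected results by exhaustive or rational
computation, never by calling the code paths they check.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

from ppio.extraction import Match
from ppio.model import Category


def brute_force_longest(matches: list[Match]) -> list[Match]:
    """Per category, enumerate every maximal set of mutually non-overlapping
    matches and select the one whose (length desc, start asc) rank tuple is
    lexicographically smallest — the canonical greedy solution."""
    kept: list[Match] = []
    by_cat: dict[Category, list[Match]] = {}
    for m in matches:
        by_cat.setdefault(m.category, []).append(m)
    for cat, ms in by_cat.items():
        order = sorted(ms, key=lambda m: (-m.length, m.span[0], m.category.name, m.surface))
        rank = {id(m): i for i, m in enumerate(order)}
        best = None
        for r in range(len(ms) + 1):
            for combo in itertools.combinations(order, r):
                if any(a.overlaps(b) for a, b in itertools.combinations(combo, 2)):
                    continue
                # maximality: no further match can be added
                if any(
                    all(not c.overlaps(m) for c in combo) for m in order if m not in combo
                ):
                    continue
                key = tuple(sorted(rank[id(m)] for m in combo))
                if best is None or key < best[0]:
                    best = (key, combo)
        if best is not None:
            kept.extend(best[1])
    kept.sort(key=lambda m: (m.span, m.category.name, m.surface))
    return kept


def random_match_set(rng: random.Random, max_matches: int = 8) -> list[Match]:
    """Random overlapping spans over a short line, two or three categories."""
    cats = [Category.INTERACTION_TYPE, Category.BIOLOGICAL_PROCESS, Category.DETECTION_METHOD]
    n = rng.randint(0, max_matches)
    out = []
    for i in range(n):
        start = rng.randint(0, 30)
        end = start + rng.randint(1, 10)
        cat = rng.choice(cats)
        out.append(Match((start, end), f"m{i}", frozenset({f"T:{i}"}), cat))
    return out


def fraction_metrics(tp: int, fp: int, fn: int):
    """Exact rational precision/recall/F from first principles."""
    p = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
    r = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    f = 2 * p * r / (p + r) if p + r else Fraction(0)
    return p, r, f


def reachability_fixed_point(edges: set[tuple[str, str]], start: str) -> set[str]:
    """Ancestors by repeated edge expansion to a fixed point."""
    reached: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = {p for (c, p) in edges if c in frontier} - reached
        reached |= nxt
        frontier = nxt
    return reached
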