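"""Precision / recall / F-score benchmarking of extracted PPI annotations.

The unit of comparison is the distinct (sentence_id, category, normalized
surface) triple: a term credited to several PPIs of one sentence counts once
(a per-PPI mode is available).  Per-category confusion counts feed

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * P * R / (P + R)

and the Total row pools TP/FP/FN across categories (micro-average); the
macro-average is reported alongside for transparency.  Any 0/0 yields 0 with
a ``degenerate`` flag so empty categories never crash a batch run.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

from .dictionary import normalize_surface
from .model import Category
from .extraction import AnnotatedPPI

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "Metrics",
    "compare",
    "compute_metrics",
    "aggregate",
    "macro_average",
    "read_gold_tsv",
    "evaluation_report",
]


@dataclass(frozen=True)
class GoldAnnotation:
    sentence_id: str
    category: Category
    term_surface: str  # normalized

    @staticmethod
    def make(sentence_id: str, category: Category, surface: str) -> "GoldAnnotation":
        return GoldAnnotation(sentence_id, category, normalize_surface(surface))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_score: float
    degenerate: bool = False


def predicted_tuples(predicted: list[AnnotatedPPI]) -> set[tuple[str, Category, str]]:
    out: set[tuple[str, Category, str]] = set()
    for ap in predicted:
        out |= ap.all_tuples()
    return out


def compare(
    predicted: list[AnnotatedPPI],
    gold: list[GoldAnnotation],
    per_ppi: bool = False,
) -> dict[Category, ConfusionCounts]:
    """Set-compare predictions against the curated gold list, per category.

    ``per_ppi=True`` scores each (PPI, category, surface) assignment
    separately instead of once per sentence; the gold list, having no PPI
    attribution, is then credited once per matching PPI.
    """
    gold_set = {(g.sentence_id, g.category, g.term_surface) for g in gold}
    counts: dict[Category, ConfusionCounts] = {}
    if not per_ppi:
        pred_set = predicted_tuples(predicted)
        for cat in Category:
            p = {t for t in pred_set if t[1] is cat}
            g = {t for t in gold_set if t[1] is cat}
            counts[cat] = ConfusionCounts(
                tp=len(p & g), fp=len(p - g), fn=len(g - p)
            )
        return counts
    # per-PPI scoring
    for cat in Category:
        tp = fp = 0
        matched_gold: set = set()
        for ap in predicted:
            for _tid, surface in ap.annotations.get(cat, ()):
                key = (ap.ppi.sentence_id, cat, surface)
                if key in gold_set:
                    tp += 1
                    matched_gold.add(key)
                else:
                    fp += 1
        fn = len({t for t in gold_set if t[1] is cat} - matched_gold)
        counts[cat] = ConfusionCounts(tp=tp, fp=fp, fn=fn)
    return counts


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall, F; 0/0 cases return 0 flagged as degenerate."""
    degenerate = False
    if c.tp + c.fp > 0:
        p = c.tp / (c.tp + c.fp)
    else:
        p, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        r = c.tp / (c.tp + c.fn)
    else:
        r, degenerate = 0.0, True
    if p + r > 0:
        f = 2 * p * r / (p + r)
    else:
        f, degenerate = 0.0, True
    return Metrics(precision=p, recall=r, f_score=f, degenerate=degenerate)


def aggregate(per_cat: dict[Category, ConfusionCounts]) -> Metrics:
    """Micro-average: pool counts across categories, then score."""
    pooled = ConfusionCounts()
    for c in per_cat.values():
        pooled = pooled + c
    return compute_metrics(pooled)


def macro_average(per_cat: dict[Category, ConfusionCounts]) -> Metrics:
    """Unweighted mean of the per-category metrics (reported for contrast)."""
    ms = [compute_metrics(c) for c in per_cat.values()]
    if not ms:
        return Metrics(0.0, 0.0, 0.0, degenerate=True)
    n = len(ms)
    return Metrics(
        precision=sum(m.precision for m in ms) / n,
        recall=sum(m.recall for m in ms) / n,
        f_score=sum(m.f_score for m in ms) / n,
        degenerate=any(m.degenerate for m in ms),
    )


# ---------------------------------------------------------------------------
# Gold-corpus and report I/O
# ---------------------------------------------------------------------------


def read_gold_tsv(path) -> list[GoldAnnotation]:
    """Columns: sentence_id, category, term_surface."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    for i, row in enumerate(csv.DictReader(rows, delimiter="\t"), start=2):
        try:
            cat = Category.from_name(row["category"])
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
        out.append(GoldAnnotation.make(row["sentence_id"], cat, row["term_surface"]))
    return out


def write_gold_tsv(gold: list[GoldAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sentence_id", "category", "term_surface"])
        for g in gold:
            w.writerow([g.sentence_id, g.category.name, g.term_surface])


def evaluation_report(per_cat: dict[Category, ConfusionCounts]) -> dict:
    """Per-category rows plus micro ('Total') and macro summary rows."""
    rows = {}
    for cat in Category:
        c = per_cat.get(cat, ConfusionCounts())
        m = compute_metrics(c)
        rows[cat.name] = {
            "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "precision": round(m.precision, 3),
            "recall": round(m.recall, 3),
            "f_score": round(m.f_score, 3),
            "degenerate": m.degenerate,
        }
    micro = aggregate(per_cat)
    macro = macro_average(per_cat)
    rows["Total"] = {
        "precision": round(micro.precision, 3),
        "recall": round(micro.recall, 3),
        "f_score": round(micro.f_score, 3),
        "degenerate": micro.degenerate,
    }
    rows["Macro"] = {
        "precision": round(macro.precision, 3),
        "recall": round(macro.recall, 3),
        "f_score": round(macro.f_score, 3),
        "degenerate": macro.degenerate,
    }
    return rows


def report_tsv(report: dict) -> str:
    """Table with one row per category and summary rows, 2-decimal scores."""
    lines = ["category\tprecision\trecall\tf_score"]
    for name, row in report.items():
        lines.append(
            f"{name}\t{row['precision']:.2f}\t{row['recall']:.2f}\t{row['f_score']:.2f}"
        )
    return "\n".join(lines) + "\n"


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2) + "\n"
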