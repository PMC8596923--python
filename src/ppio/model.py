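"""Event-model PPI ontology: types, OBO 1.2 I/O, validation, statistics.

A protein-protein interaction (PPI) is treated as a molecular event with six
facets, each served by one sub-ontology branch: the interactor (*who*), the
biological process (*when*), the subcellular location (*where*), the
interaction type (*how*), the biological function (*what*) and the detection
method (*which*).  The ontology is a term graph over a restricted relationship
vocabulary (``is_a``, ``part_of``, ``proper_part_of``) with one root term per
facet; every non-obsolete term must reach exactly one root.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "Category",
    "Term",
    "Relationship",
    "Ontology",
    "OntologyStats",
    "ValidationIssue",
    "OboParseError",
    "ALLOWED_REL_TYPES",
    "parse_obo",
    "parse_obo_string",
    "write_obo",
    "write_obo_string",
    "validate",
    "stats",
    "ancestors",
]

ALLOWED_REL_TYPES = ("is_a", "part_of", "proper_part_of")


class Category(enum.Enum):
    """The six annotation facets of a PPI event.

    Each category answers one question about the event and owns one root
    term of the ontology.
    """

    INTERACTOR = ("who", "interactor")
    BIOLOGICAL_PROCESS = ("when", "biological process")
    SUBCELLULAR_LOCATION = ("where", "subcellular location")
    INTERACTION_TYPE = ("how", "interaction type")
    BIOLOGICAL_FUNCTION = ("what", "biological function")
    DETECTION_METHOD = ("which", "detection method")

    def __init__(self, event_role: str, label: str):
        self.event_role = event_role
        self.label = label

    @classmethod
    def from_label(cls, label: str) -> "Category | None":
        key = " ".join(label.lower().split())
        for cat in cls:
            if cat.label == key:
                return cat
        return None

    @classmethod
    def from_name(cls, name: str) -> "Category":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown category: {name!r}") from None


@dataclass
class Term:
    """One ontology concept.

    ``source_ref`` carries the accession of the term in its originating
    ontology (stored as an OBO xref); ``extra_tags`` preserves any OBO tag
    lines this package does not interpret, verbatim, for lossless round-trip.
    """

    id: str
    name: str
    synonyms: set[str] = field(default_factory=set)
    definition: str | None = None
    source_ref: str | None = None
    category: Category | None = None
    is_obsolete: bool = False
    extra_tags: tuple[str, ...] = ()

    def surfaces(self) -> set[str]:
        """Primary name plus all synonyms."""
        return {self.name} | self.synonyms

    # Terms live in id-keyed sets during construction; identity is the id.
    def __hash__(self) -> int:
        return hash(self.id)


@dataclass(frozen=True)
class Relationship:
    """A directed child -> parent edge with a typed relation."""

    child: str
    parent: str
    rel_type: str


@dataclass
class OntologyStats:
    per_category_count: dict[Category, int]
    total: int


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "error" | "warning"
    rule: str
    term_id: str | None
    message: str

    def to_json(self) -> dict:
        return {
            "level": self.level,
            "rule": self.rule,
            "term_id": self.term_id,
            "message": self.message,
        }


class OboParseError(ValueError):
    """Raised on a malformed OBO stanza; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class Ontology:
    """A six-rooted term graph.

    ``roots`` maps each category present to its root term id.  Partial or
    empty root sets are legal (e.g. a generic source ontology or a single
    sub-ontology fragment); the category-consistency validation rule applies
    only to the designated roots.
    """

    def __init__(
        self,
        terms: dict[str, Term] | None = None,
        relationships: Iterable[Relationship] = (),
        roots: dict[Category, str] | None = None,
        header_lines: tuple[str, ...] = (),
    ):
        self.terms: dict[str, Term] = dict(terms or {})
        self.relationships: set[Relationship] = set(relationships)
        self.roots: dict[Category, str] = dict(roots or {})
        self.header_lines = tuple(header_lines)

    # -- graph views -------------------------------------------------------

    def parent_graph(self, rel_types: Iterable[str] | None = None) -> nx.DiGraph:
        """Directed graph with an edge child -> parent per relationship."""
        wanted = set(rel_types) if rel_types is not None else None
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for rel in self.relationships:
            if wanted is None or rel.rel_type in wanted:
                g.add_edge(rel.child, rel.parent)
        return g

    def add_term(self, term: Term) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def resolve_categories(self) -> None:
        """Assign each term the category of the unique root it reaches.

        Terms reaching zero or multiple roots keep ``category=None``; the
        validator reports them.
        """
        if not self.roots:
            return
        root_of = {tid: cat for cat, tid in self.roots.items()}
        g = self.parent_graph(ALLOWED_REL_TYPES)
        for tid, term in self.terms.items():
            if tid in root_of:
                term.category = root_of[tid]
                continue
            if tid not in g:
                term.category = None
                continue
            reached = {root_of[a] for a in nx.descendants(g, tid) if a in root_of}
            term.category = reached.pop() if len(reached) == 1 else None

    def equals(self, other: "Ontology") -> bool:
        """Equality on (terms, relationships, roots)."""
        return (
            self.terms == other.terms
            and self.relationships == other.relationships
            and self.roots == other.roots
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Ontology: {len(self.terms)} terms, {len(self.relationships)} relationships>"


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file I/O
# ---------------------------------------------------------------------------

_KNOWN_TAGS = {"id", "name", "def", "synonym", "is_a", "relationship", "is_obsolete", "xref"}
_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')
_DEF_RE = _SYNONYM_RE


def _strip_comment(value: str) -> str:
    # OBO trailing comments start at " ! " (or "\t!"); a bare "!" inside a
    # quoted string is not a comment, but known tags here are unquoted ids.
    idx = value.find(" ! ")
    if idx == -1 and value.endswith(" !"):
        idx = len(value) - 2
    return value[:idx].strip() if idx != -1 else value.strip()


def parse_obo_string(text: str, source: str = "<string>") -> Ontology:
    """Parse OBO 1.2 flat text into an :class:`Ontology`.

    Unknown tags are preserved verbatim on each term; ``[Typedef]`` and other
    non-Term stanzas are preserved as header-level lines.  Obsolete term
    stanzas are retained with ``is_obsolete=True``.  Root terms are recognised
    by name (the six category labels, case-insensitive).
    """
    onto = Ontology()
    header: list[str] = []
    current: dict | None = None
    current_stanza_type: str | None = None
    passthrough: list[str] = []  # non-[Term] stanzas, preserved verbatim

    def flush():
        nonlocal current
        if current is None:
            return
        if current["id"] is None:
            raise OboParseError("term stanza without id", current["start_line"])
        if not current["name"]:
            raise OboParseError(
                f"term {current['id']!r} has no name", current["start_line"]
            )
        term = Term(
            id=current["id"],
            name=current["name"],
            synonyms=current["synonyms"],
            definition=current["definition"],
            source_ref=current["source_ref"],
            is_obsolete=current["is_obsolete"],
            extra_tags=tuple(current["extra"]),
        )
        if term.id in onto.terms:
            raise OboParseError(f"duplicate term id {term.id!r}", current["start_line"])
        onto.terms[term.id] = term
        for rel in current["rels"]:
            onto.relationships.add(rel)
        current = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            flush()
            current_stanza_type = stripped[1:-1]
            if current_stanza_type == "Term":
                current = {
                    "id": None,
                    "name": "",
                    "synonyms": set(),
                    "definition": None,
                    "source_ref": None,
                    "is_obsolete": False,
                    "extra": [],
                    "rels": [],
                    "start_line": lineno,
                }
            else:
                passthrough.append(stripped)
            continue
        if not stripped or stripped.startswith("!"):
            continue
        if current_stanza_type is None:
            header.append(stripped)
            continue
        if current_stanza_type != "Term":
            passthrough.append(stripped)
            continue
        if ":" not in stripped:
            raise OboParseError(f"malformed tag line {stripped!r}", lineno)
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.strip()
        assert current is not None
        if tag == "id":
            current["id"] = _strip_comment(value)
            if not current["id"]:
                raise OboParseError("empty term id", lineno)
        elif tag == "name":
            current["name"] = _strip_comment(value)
        elif tag == "def":
            m = _DEF_RE.match(value)
            if not m:
                raise OboParseError(f"malformed def line {stripped!r}", lineno)
            current["definition"] = m.group("text").replace('\\"', '"')
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(f"malformed synonym line {stripped!r}", lineno)
            current["synonyms"].add(m.group("text").replace('\\"', '"'))
        elif tag == "xref":
            current["source_ref"] = _strip_comment(value)
        elif tag == "is_obsolete":
            current["is_obsolete"] = _strip_comment(value).lower() == "true"
        elif tag == "is_a":
            parent = _strip_comment(value)
            if not parent:
                raise OboParseError("is_a with empty target", lineno)
            current["rels"].append(Relationship(current["id"], parent, "is_a"))
        elif tag == "relationship":
            body = _strip_comment(value)
            parts = body.split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship line {stripped!r}", lineno)
            current["rels"].append(Relationship(current["id"], parts[1], parts[0]))
        else:
            current["extra"].append(stripped)
    flush()

    onto.header_lines = tuple(header)
    if passthrough:
        # Preserved, but not interpreted: tack onto the header block.
        onto.header_lines = onto.header_lines + ("",) + tuple(passthrough)

    # Root discovery by canonical category label.
    for term in onto.terms.values():
        cat = Category.from_label(term.name)
        if cat is not None and cat not in onto.roots:
            onto.roots[cat] = term.id
    onto.resolve_categories()
    return onto


def parse_obo(path) -> Ontology:
    """Read an OBO 1.2 flat file from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_obo_string(fh.read(), source=str(path))


def _escape_quoted(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def write_obo_string(onto: Ontology) -> str:
    """Serialize canonically: stanzas sorted by id, tags in fixed order.

    Writing is byte-deterministic and ``parse_obo(write_obo(x))`` equals ``x``
    on (terms, relationships, roots).
    """
    out: list[str] = []
    header = [h for h in onto.header_lines if h]
    if not any(h.startswith("format-version:") for h in header):
        out.append("format-version: 1.2")
    out.extend(header)
    rels_by_child: dict[str, list[Relationship]] = {}
    for rel in onto.relationships:
        rels_by_child.setdefault(rel.child, []).append(rel)
    for tid in sorted(onto.terms):
        term = onto.terms[tid]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {term.id}")
        out.append(f"name: {term.name}")
        if term.definition is not None:
            out.append(f'def: "{_escape_quoted(term.definition)}" []')
        for syn in sorted(term.synonyms):
            out.append(f'synonym: "{_escape_quoted(syn)}" RELATED []')
        if term.source_ref is not None:
            out.append(f"xref: {term.source_ref}")
        for rel in sorted(rels_by_child.get(tid, []), key=lambda r: (r.rel_type, r.parent)):
            if rel.rel_type == "is_a":
                out.append(f"is_a: {rel.parent}")
            else:
                out.append(f"relationship: {rel.rel_type} {rel.parent}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        out.extend(term.extra_tags)
    return "\n".join(out) + "\n"


def write_obo(onto: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_obo_string(onto))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(onto: Ontology) -> list[ValidationIssue]:
    """Check every structural invariant; violations become report entries.

    Rules: non-empty names, synonyms distinct from the name, relationship
    vocabulary restricted to is_a/part_of/proper_part_of, no self-edges,
    endpoints present, acyclic is_a subgraph (and acyclic union graph), and —
    when roots are designated — every non-root, non-obsolete term reaching
    exactly one root.
    """
    issues: list[ValidationIssue] = []

    def err(rule: str, term_id: str | None, msg: str):
        issues.append(ValidationIssue("error", rule, term_id, msg))

    for tid, term in onto.terms.items():
        if not tid:
            err("empty id", tid, "term with empty id")
        if not term.name:
            err("empty name", tid, f"term {tid} has empty name")
        if term.name in term.synonyms:
            err("name in synonyms", tid, f"term {tid} lists its name as a synonym")

    for rel in onto.relationships:
        if rel.rel_type not in ALLOWED_REL_TYPES:
            err(
                "disallowed relationship type",
                rel.child,
                f"{rel.child} -[{rel.rel_type}]-> {rel.parent}: rel_type must be one of {ALLOWED_REL_TYPES}",
            )
        if rel.child == rel.parent:
            err("self relationship", rel.child, f"{rel.child} relates to itself")
        for endpoint in (rel.child, rel.parent):
            if endpoint not in onto.terms:
                err(
                    "unknown relationship endpoint",
                    endpoint,
                    f"relationship {rel.child} -> {rel.parent} references missing term {endpoint}",
                )

    known_rels = [
        r
        for r in onto.relationships
        if r.child in onto.terms and r.parent in onto.terms and r.child != r.parent
    ]
    is_a_graph = nx.DiGraph()
    is_a_graph.add_nodes_from(onto.terms)
    is_a_graph.add_edges_from((r.child, r.parent) for r in known_rels if r.rel_type == "is_a")
    for cycle in nx.simple_cycles(is_a_graph):
        err("is_a cycle", cycle[0], "is_a cycle: " + " -> ".join(cycle + [cycle[0]]))
    union_graph = nx.DiGraph()
    union_graph.add_nodes_from(onto.terms)
    union_graph.add_edges_from((r.child, r.parent) for r in known_rels)
    if not nx.is_directed_acyclic_graph(union_graph):
        if nx.is_directed_acyclic_graph(is_a_graph):
            cyc = next(iter(nx.simple_cycles(union_graph)))
            err("relationship cycle", cyc[0], "cycle in combined relationship graph: " + " -> ".join(cyc + [cyc[0]]))

    if onto.roots and nx.is_directed_acyclic_graph(union_graph):
        root_ids = set(onto.roots.values())
        for tid, term in onto.terms.items():
            if tid in root_ids or term.is_obsolete:
                continue
            reached = root_ids & nx.descendants(union_graph, tid)
            if len(reached) == 0:
                err("unreachable from roots", tid, f"term {tid} reaches no category root")
            elif len(reached) > 1:
                err(
                    "ambiguous category",
                    tid,
                    f"term {tid} reaches multiple category roots: {sorted(reached)}",
                )
    return issues


def report_text(issues: list[ValidationIssue]) -> str:
    if not issues:
        return "OK: no validation issues\n"
    return "\n".join(f"{i.level.upper()}\t{i.rule}\t{i.term_id or '-'}\t{i.message}" for i in issues) + "\n"


def report_json(issues: list[ValidationIssue]) -> str:
    return json.dumps([i.to_json() for i in issues], indent=2) + "\n"


# ---------------------------------------------------------------------------
# Summaries and traversal
# ---------------------------------------------------------------------------


def stats(onto: Ontology) -> OntologyStats:
    """Count non-obsolete terms per category (roots included)."""
    counts = {cat: 0 for cat in Category}
    for term in onto.terms.values():
        if term.is_obsolete or term.category is None:
            continue
        counts[term.category] += 1
    return OntologyStats(per_category_count=counts, total=sum(counts.values()))


def ancestors(onto: Ontology, term_id: str) -> set[str]:
    """Transitive ancestors of ``term_id`` over all three relationship types."""
    if term_id not in onto.terms:
        raise KeyError(f"unknown term id {term_id!r}")
    g = onto.parent_graph(ALLOWED_REL_TYPES)
    return set(nx.descendants(g, term_id))
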