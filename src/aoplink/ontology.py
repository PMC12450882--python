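"""Gene Ontology handling: OBO parsing, identifier normalization, descendant closures.

The mechanistic term sets used throughout the package ("primary GO and child GO
terms" of an AOP event) are built by expanding a parent GO Biological Process
term into its descendant closure over ``is_a`` (optionally ``part_of``)
relations.  This module provides the small ontology container that supports
that expansion, a strict OBO 1.2/1.4 flat-file reader with line-accurate
errors, and identifier normalization with alt_id (merged-term) resolution.

Only ``is_a`` and ``part_of`` relations are retained; the package never
reasons over ``regulates``-style relations or cross-ontology links.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

_GO_PATTERN = re.compile(r"^\s*(?:GO[:_ ]?)(\d{1,7})\s*$", re.IGNORECASE)


class OboParseError(ValueError):
    """Raised on malformed OBO input; the message names the offending line."""


class UnknownTermError(KeyError):
    """Raised when a term id is not present in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single GO term.

    ``term_id`` is always the canonical zero-padded form ``GO:NNNNNNN``.
    Obsolete terms are retained (so lookups can explain themselves) but carry
    no relations in the graph.
    """

    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """A GO term DAG with typed child→parent edges.

    Attributes
    ----------
    terms:
        Mapping from canonical term id to :class:`OntologyTerm`.
    edges:
        Set of ``(child_id, relation, parent_id)`` triples with relation in
        ``{"is_a", "part_of"}``.
    alt_ids:
        Mapping from secondary (merged) id to canonical id.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    # parent_id -> relation -> set of child ids (built lazily)
    _children: dict[str, dict[str, set[str]]] | None = field(
        default=None, repr=False, compare=False
    )
    _parents: dict[str, dict[str, set[str]]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def namespace_counts(self) -> dict[str, int]:
        """Number of non-obsolete terms per namespace."""
        counts: dict[str, int] = {ns: 0 for ns in NAMESPACES}
        for term in self.terms.values():
            if not term.obsolete:
                counts[term.namespace] = counts.get(term.namespace, 0) + 1
        return counts

    def resolve(self, term_id: str) -> str:
        """Map a canonical or alternate id to its canonical id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def _adjacency(self) -> tuple[dict, dict]:
        if self._children is None or self._parents is None:
            children: dict[str, dict[str, set[str]]] = {}
            parents: dict[str, dict[str, set[str]]] = {}
            for child, rel, parent in self.edges:
                children.setdefault(parent, {}).setdefault(rel, set()).add(child)
                parents.setdefault(child, {}).setdefault(rel, set()).add(parent)
            object.__setattr__(self, "_children", children)
            object.__setattr__(self, "_parents", parents)
        return self._children, self._parents

    def invalidate_cache(self) -> None:
        self._children = None
        self._parents = None

    def children(self, term_id: str, relations: Iterable[str] = ("is_a",)) -> set[str]:
        """Direct children of ``term_id`` over the chosen relations."""
        term_id = self.resolve(term_id)
        adj, _ = self._adjacency()
        out: set[str] = set()
        for rel in relations:
            out |= adj.get(term_id, {}).get(rel, set())
        return out

    def parents(self, term_id: str, relations: Iterable[str] = ("is_a",)) -> set[str]:
        term_id = self.resolve(term_id)
        _, adj = self._adjacency()
        out: set[str] = set()
        for rel in relations:
            out |= adj.get(term_id, {}).get(rel, set())
        return out

    def ancestors(self, term_id: str, relations: Iterable[str] = ("is_a",)) -> set[str]:
        """Reflexive transitive closure towards the root(s)."""
        start = self.resolve(term_id)
        seen = {start}
        frontier = [start]
        while frontier:
            nxt: list[str] = []
            for t in frontier:
                for p in self.parents(t, relations):
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            frontier = nxt
        return seen

    def roots(self, namespace: str = "biological_process") -> set[str]:
        """Non-obsolete terms of ``namespace`` without an is_a parent."""
        return {
            t.term_id
            for t in self.terms.values()
            if t.namespace == namespace
            and not t.obsolete
            and not self.parents(t.term_id, ("is_a",))
        }


def normalize_term_id(raw: str, graph: OntologyGraph | None = None) -> str:
    """Normalize a GO accession to the canonical ``GO:NNNNNNN`` form.

    Accepts common dialects (``go:7165``, ``go_0007165``, stray whitespace)
    and, when ``graph`` is supplied, resolves alt_ids to their canonical
    term.  Anything that is not a GO accession (e.g. a gene symbol) raises
    ``ValueError``.
    """
    if not isinstance(raw, str):
        raise ValueError(f"not a GO term identifier: {raw!r}")
    m = _GO_PATTERN.match(raw)
    if m is None:
        raise ValueError(f"not a GO term identifier: {raw!r}")
    term_id = f"GO:{int(m.group(1)):07d}"
    if graph is not None and term_id in graph:
        return graph.resolve(term_id)
    return term_id


def parse_obo(stream: TextIO | Iterable[str]) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are interpreted; ``is_a`` and
    ``relationship: part_of`` edges are captured, ``alt_id`` values are
    mapped to their canonical term and obsolete terms are kept flagged but
    stripped of relations (with a logged warning).

    Raises
    ------
    OboParseError
        On a malformed stanza (naming the line) or a duplicate canonical id.
    """
    graph = OntologyGraph()
    pending_edges: list[tuple[str, str, str, int]] = []

    in_term = False
    current: dict | None = None
    stanza_line = 0

    def finish(current: dict | None) -> None:
        if current is None:
            return
        term_id = current.get("id")
        if term_id is None:
            raise OboParseError(
                f"line {current['_line']}: [Term] stanza without an id"
            )
        if term_id in graph.terms:
            raise OboParseError(
                f"line {current['_line']}: duplicate canonical id {term_id}"
            )
        obsolete = current.get("obsolete", False)
        graph.terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=current.get("name", ""),
            namespace=current.get("namespace", "biological_process"),
            obsolete=obsolete,
        )
        for alt in current.get("alt_ids", []):
            graph.alt_ids[alt] = term_id
        if obsolete:
            if current.get("edges"):
                logger.warning(
                    "obsolete term %s: dropping %d relation(s)",
                    term_id,
                    len(current["edges"]),
                )
        else:
            for rel, parent, lineno in current.get("edges", []):
                pending_edges.append((term_id, rel, parent, lineno))

    for lineno, rawline in enumerate(stream, start=1):
        line = rawline.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            finish(current)
            current = None
            in_term = line == "[Term]"
            stanza_line = lineno
            if in_term:
                current = {"_line": lineno, "alt_ids": [], "edges": []}
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        if not in_term:
            continue  # header or other stanza types
        tag, value = (s.strip() for s in line.split(":", 1))
        assert current is not None
        try:
            if tag == "id":
                current["id"] = normalize_term_id(value)
            elif tag == "name":
                current["name"] = value
            elif tag == "namespace":
                current["namespace"] = value
            elif tag == "alt_id":
                current["alt_ids"].append(normalize_term_id(value))
            elif tag == "is_a":
                current["edges"].append(("is_a", normalize_term_id(value), lineno))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(
                        f"line {lineno}: malformed relationship {value!r}"
                    )
                if parts[0] == "part_of":
                    current["edges"].append(
                        ("part_of", normalize_term_id(parts[1]), lineno)
                    )
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
        except ValueError as exc:
            raise OboParseError(f"line {lineno}: {exc}") from exc
    finish(current)

    for child, rel, parent, lineno in pending_edges:
        if parent in graph.alt_ids:
            parent = graph.alt_ids[parent]
        if parent not in graph.terms:
            raise OboParseError(
                f"line {lineno}: edge references unknown term {parent}"
            )
        if graph.terms[parent].obsolete:
            logger.warning("dropping edge %s -> obsolete parent %s", child, parent)
            continue
        graph.edges.add((child, rel, parent))
    graph.invalidate_cache()
    _ = stanza_line  # silence linters; retained for error context symmetry
    return graph


def descendants(
    graph: OntologyGraph,
    term_id: str,
    relations: Iterable[str] = ("is_a",),
) -> set[str]:
    """Reflexive transitive descendant closure of ``term_id``.

    The term itself is always a member; traversal follows the chosen
    relations child-ward and is restricted to the term's own namespace.
    Obsolete terms never appear in the closure.
    """
    start = graph.resolve(term_id)
    namespace = graph.terms[start].namespace
    relations = tuple(relations)
    seen = {start}
    frontier = [start]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for c in graph.children(t, relations):
                if c in seen:
                    continue
                child_term = graph.terms[c]
                if child_term.obsolete or child_term.namespace != namespace:
                    continue
                seen.add(c)
                nxt.append(c)
        frontier = nxt
    if graph.terms[start].obsolete:
        return set()
    return seen


def expand_terms(
    graph: OntologyGraph,
    term_ids: Iterable[str],
    relations: Iterable[str] = ("is_a",),
    mode: str = "descendants",
) -> dict[str, set[str]]:
    """Expand each parent term into parent + children.

    ``mode='descendants'`` (default) takes the full closure; ``mode='children'``
    only the direct children plus the parent itself.
    """
    if mode not in ("descendants", "children"):
        raise ValueError(f"unknown expand mode: {mode!r}")
    out: dict[str, set[str]] = {}
    for tid in term_ids:
        canon = graph.resolve(tid)
        if mode == "descendants":
            out[canon] = descendants(graph, canon, relations)
        else:
            out[canon] = {canon} | graph.children(canon, relations)
    return out


def is_acyclic(graph: OntologyGraph, relation: str = "is_a") -> bool:
    """Check that the non-obsolete subgraph has no cycle over ``relation``."""
    indeg: dict[str, int] = {
        t: 0 for t, term in graph.terms.items() if not term.obsolete
    }
    children_of: dict[str, list[str]] = {t: [] for t in indeg}
    for child, rel, parent in graph.edges:
        if rel != relation or child not in indeg or parent not in indeg:
            continue
        indeg[child] += 1
        children_of[parent].append(child)
    queue = [t for t, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        t = queue.pop()
        seen += 1
        for c in children_of[t]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(indeg)
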