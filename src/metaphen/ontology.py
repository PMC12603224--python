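"""Phenotype ontology loading, traversal and count aggregation.

The analyses in this package treat the phenotype ontology as a directed
acyclic is-a graph over CURIE-identified terms (``HP:0001337`` and friends).
Only is-a edges are used: part-of and other relationship types carry no
meaning for subsumption of clinical signs and are dropped at parse time.

Cohort-level phenotype counts cannot be union-propagated up the hierarchy
because per-case overlap between sibling terms is unknown (the same patient
may be counted under both "resting tremor" and "postural tremor").
:func:`aggregate_to_term` therefore offers two explicit modes: ``max`` (a
conservative lower bound on the parent-term count) and ``capped_sum`` (an
upper bound, capped so that presence never exceeds assessment).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Mapping, Sequence

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "TermMapping",
    "OntologyError",
    "CycleError",
    "UnknownTermError",
    "UnmappedLabelError",
    "parse_ontology",
    "load_mini_ontology",
    "ancestors",
    "descendants",
    "aggregate_to_term",
    "map_label",
]

AggregationMode = Literal["max", "capped_sum"]


class OntologyError(ValueError):
    """Malformed ontology input."""


class CycleError(OntologyError):
    """The is-a graph contains a cycle; carries one offending term id."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"is-a cycle detected involving term {member!r}")


class UnknownTermError(KeyError):
    """A term id does not resolve in the graph."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"unknown ontology term {term_id!r}")


class UnmappedLabelError(KeyError):
    """A free-text label has no row in the term mapping."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"no term mapping for label {label!r}")


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term (CURIE id, label, is-a parents)."""

    id: str
    name: str
    parent_ids: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: str | None = None


class OntologyGraph:
    """Directed acyclic is-a graph of phenotype terms.

    Parameters
    ----------
    terms
        Iterable of :class:`OntologyTerm`. Parent references must resolve
        within the iterable and the resulting graph must be acyclic; both
        conditions are checked at construction.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.id in self.terms:
                raise OntologyError(f"duplicate term id {term.id!r}")
            self.terms[term.id] = term
        self._children: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for term in self.terms.values():
            for pid in term.parent_ids:
                if pid not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} references unknown parent {pid!r}"
                    )
                self._children[pid].add(term.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for pid in term.parent_ids:
                g.add_edge(term.id, pid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError(cycle[0][0])

    @property
    def root_ids(self) -> list[str]:
        """Ids of terms with no non-obsolete parents, sorted."""
        return sorted(
            t.id for t in self.terms.values() if not t.parent_ids and not t.obsolete
        )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, term_id: str) -> str:
        return self[term_id].name

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def children(self, term_id: str) -> set[str]:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return set(self._children[term_id])

    def resolve(self, term_id: str) -> str:
        """Resolve obsolete ids via replaced-by; reject dead obsoletes."""
        term = self[term_id]
        if not term.obsolete:
            return term_id
        if term.replaced_by and term.replaced_by in self.terms:
            return self.resolve(term.replaced_by)
        raise OntologyError(
            f"term {term_id!r} is obsolete and has no replacement in this graph"
        )

    def to_json(self) -> str:
        """Serialise to the nodes/edges ontology-graph JSON dialect."""
        nodes = [
            {
                "id": t.id,
                "name": t.name,
                **({"obsolete": True} if t.obsolete else {}),
                **({"replaced_by": t.replaced_by} if t.replaced_by else {}),
            }
            for t in sorted(self.terms.values(), key=lambda t: t.id)
        ]
        edges = [
            {"child": c, "parent": p}
            for c, p in sorted(
                (t.id, p) for t in self.terms.values() for p in t.parent_ids
            )
        ]
        return json.dumps({"nodes": nodes, "edges": edges}, indent=1)


@dataclass
class TermMapping:
    """Curated table mapping free-text source labels to CURIE term ids.

    Lookup is exact after case-folding and whitespace normalisation; no
    fuzzy matching is attempted (mirrors a hand-curated descriptor table).
    """

    rows: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], graph: OntologyGraph | None = None
    ) -> "TermMapping":
        rows: dict[str, str] = {}
        for label, term_id in pairs:
            key = _normalise_label(label)
            if key in rows:
                raise OntologyError(f"duplicate source label {label!r} in mapping")
            if graph is not None:
                term_id = graph.resolve(term_id)
            rows[key] = term_id
        return cls(rows)


def _normalise_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


def map_label(label: str, mapping: TermMapping) -> str:
    """Look up a free-text descriptor in a curated mapping table."""
    key = _normalise_label(label)
    try:
        return mapping.rows[key]
    except KeyError:
        raise UnmappedLabelError(label) from None


def parse_ontology(
    source: str | IO[str], format: Literal["obo", "graph-json"] = "obo"
) -> OntologyGraph:
    """Parse an ontology from OBO 1.2 text or nodes/edges graph JSON.

    Only is-a relations are loaded. Obsolete terms are retained and
    flagged; their replaced-by target (if any) is recorded so mappings can
    be migrated across releases.
    """
    if format == "obo":
        return _parse_obo(source)
    if format == "graph-json":
        return _parse_graph_json(source)
    raise ValueError(f"unknown ontology format {format!r}")


def _parse_obo(source: str | IO[str]) -> OntologyGraph:
    graph = obonet.read_obo(source, ignore_obsolete=False)
    terms = []
    for node_id, data in graph.nodes(data=True):
        parents = tuple(
            sorted(
                v
                for _, v, key in graph.out_edges(node_id, keys=True)
                if key == "is_a"
            )
        )
        replaced = data.get("replaced_by") or []
        terms.append(
            OntologyTerm(
                id=node_id,
                name=data.get("name", node_id),
                parent_ids=parents,
                obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
                replaced_by=replaced[0] if replaced else None,
            )
        )
    return OntologyGraph(terms)


def _parse_graph_json(source: str | IO[str]) -> OntologyGraph:
    text = source if isinstance(source, str) else source.read()
    doc = json.loads(text)
    parents: dict[str, list[str]] = {}
    for edge in doc.get("edges", []):
        parents.setdefault(edge["child"], []).append(edge["parent"])
    terms = [
        OntologyTerm(
            id=node["id"],
            name=node.get("name", node["id"]),
            parent_ids=tuple(sorted(parents.get(node["id"], []))),
            obsolete=bool(node.get("obsolete", False)),
            replaced_by=node.get("replaced_by"),
        )
        for node in doc["nodes"]
    ]
    return OntologyGraph(terms)


def load_mini_ontology() -> OntologyGraph:
    """Load the bundled ~40-term mini phenotype ontology fixture."""
    from importlib.resources import files

    path = files("metaphen.data").joinpath("mini_hpo.obo")
    return parse_ontology(str(path), format="obo")


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Transitive is-a closure of ``term_id``, excluding the term itself."""
    start = graph[term_id].id
    seen: set[str] = set()
    stack = list(graph[start].parent_ids)
    while stack:
        tid = stack.pop()
        if tid in seen:
            continue
        seen.add(tid)
        stack.extend(graph[tid].parent_ids)
    return seen


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """All terms whose ancestor closure contains ``term_id``."""
    if term_id not in graph:
        raise UnknownTermError(term_id)
    seen: set[str] = set()
    stack = list(graph.children(term_id))
    while stack:
        tid = stack.pop()
        if tid in seen:
            continue
        seen.add(tid)
        stack.extend(graph.children(tid))
    return seen


def aggregate_to_term(
    observations: Sequence[tuple[str, int, int]],
    target: str,
    graph: OntologyGraph,
    mode: AggregationMode = "max",
) -> tuple[int, int]:
    """Aggregate (term, n_present, n_assessed) counts onto an ancestor term.

    ``max`` takes the largest contributing count (lower bound on the target
    term: at least that many cases carry *some* descendant sign);
    ``capped_sum`` sums presence counts and caps at the largest assessment
    denominator (upper bound, assuming no per-case overlap).
    """
    if not observations:
        raise ValueError("no observations to aggregate")
    subtree = descendants(graph, target) | {target}
    for term_id, n_present, n_assessed in observations:
        if term_id not in subtree:
            raise OntologyError(
                f"observation term {term_id!r} is outside the subtree of {target!r}"
            )
        if n_present > n_assessed:
            raise ValueError(
                f"{term_id}: n_present {n_present} exceeds n_assessed {n_assessed}"
            )
    n_assessed = max(obs[2] for obs in observations)
    if mode == "max":
        n_present = max(obs[1] for obs in observations)
    elif mode == "capped_sum":
        n_present = min(sum(obs[1] for obs in observations), n_assessed)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return n_present, n_assessed
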