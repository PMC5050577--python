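"""Body-part concept graphs: partonomy and laterality queries, and seeded
module extraction.

A :class:`ConceptGraph` holds anatomical concepts in an acyclic ``is_a``
taxonomy plus typed property edges (``constitutional_part``,
``nerve_supply``, ``articulates_with``, ...). Property types may be flagged
symmetric — ``articulates_with`` and ``continuous_with`` are by default —
in which case an edge (a, b) answers queries in both directions without
storing its mirror.

Module extraction derives a small self-connected subgraph from seed
concepts: the seeds with their full upper ``is_a`` hierarchy, plus nodes
reachable over whitelisted property edges within a hop limit, minus an
explicit removal list, followed by iterated orphan cleanup (nodes left
without any edge into the kept set are dropped until a fixpoint). This is
how a large reference anatomy is cut down to the handful of concepts a
treatment protocol actually mentions, small enough for interactive
reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "ConceptNode",
    "ConceptGraph",
    "ExtractionConfig",
    "UnknownConceptError",
    "DEFAULT_SYMMETRIC_TYPES",
    "parts_of",
    "laterality_of",
    "extract_module",
]

DEFAULT_SYMMETRIC_TYPES = frozenset({"articulates_with", "continuous_with"})


class UnknownConceptError(KeyError):
    pass


@dataclass(frozen=True)
class ConceptNode:
    id: str
    label: str = ""
    external_codes: tuple[tuple[str, str], ...] = ()
    laterality: Optional[str] = None  # "left" | "right" | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "external_codes", tuple(map(tuple, self.external_codes)))
        if self.laterality not in (None, "left", "right"):
            raise ValueError(f"laterality must be left/right/None, got {self.laterality!r}")


class ConceptGraph:
    """Anatomy concept graph: an acyclic is_a taxonomy plus typed property
    edges with per-type symmetry."""

    def __init__(self, symmetric_types: Iterable[str] = DEFAULT_SYMMETRIC_TYPES):
        self.nodes: dict[str, ConceptNode] = {}
        self._isa = nx.DiGraph()  # edge child -> parent
        self._props = nx.MultiDiGraph()
        self.symmetric_types = set(symmetric_types)

    # -- construction ------------------------------------------------------

    def add_node(self, node: ConceptNode) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate concept id {node.id!r}")
        self.nodes[node.id] = node
        self._isa.add_node(node.id)
        self._props.add_node(node.id)

    def add_is_a(self, child: str, parent: str) -> None:
        self._require(child), self._require(parent)
        self._isa.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._isa):
            self._isa.remove_edge(child, parent)
            raise ValueError(f"is_a edge {child!r} -> {parent!r} would create a cycle")

    def add_edge(self, src: str, edge_type: str, dst: str) -> None:
        self._require(src), self._require(dst)
        self._props.add_edge(src, dst, key=edge_type)

    def _require(self, cid: str) -> None:
        if cid not in self.nodes:
            raise UnknownConceptError(f"unknown concept {cid!r}")

    # -- queries -----------------------------------------------------------

    def parents(self, cid: str) -> set[str]:
        self._require(cid)
        return set(self._isa.successors(cid))

    def ancestors(self, cid: str) -> set[str]:
        """All transitive is_a ancestors (the upper hierarchy)."""
        self._require(cid)
        return set(nx.descendants(self._isa, cid))

    def targets(self, cid: str, edge_type: str) -> set[str]:
        """Targets of ``edge_type`` edges from ``cid``; for symmetric types
        the edge is traversable from either endpoint."""
        self._require(cid)
        out = {v for _, v, k in self._props.out_edges(cid, keys=True) if k == edge_type}
        if edge_type in self.symmetric_types:
            out |= {u for u, _, k in self._props.in_edges(cid, keys=True) if k == edge_type}
        return out

    def neighbors(self, cid: str, edge_types: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for t in edge_types:
            out |= self.targets(cid, t)
        return out

    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, k, v) for u, v, k in self._props.edges(keys=True)]

    def is_a_edges(self) -> list[tuple[str, str]]:
        return list(self._isa.edges())

    def __contains__(self, cid: str) -> bool:
        return cid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    # -- subgraph ----------------------------------------------------------

    def subgraph(self, keep: set[str]) -> "ConceptGraph":
        g = ConceptGraph(self.symmetric_types)
        for cid in sorted(keep):
            g.add_node(self.nodes[cid])
        for child, parent in self._isa.edges():
            if child in keep and parent in keep:
                g.add_is_a(child, parent)
        for u, v, k in self._props.edges(keys=True):
            if u in keep and v in keep:
                g.add_edge(u, k, v)
        return g


@dataclass(frozen=True)
class ExtractionConfig:
    """Arguments of the module extractor; ``hop_limit`` bounds traversal of
    whitelisted property edges beyond the seeds' upper hierarchy."""

    seeds: frozenset[str]
    property_types: frozenset[str] = frozenset()
    hop_limit: int = 1
    removal_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "property_types", frozenset(self.property_types))
        object.__setattr__(self, "removal_list", frozenset(self.removal_list))
        if not self.seeds:
            raise ValueError("at least one seed concept is required")
        if self.hop_limit < 0:
            raise ValueError("hop_limit must be >= 0")


def parts_of(graph: ConceptGraph, concept_id: str, transitive: bool = False) -> list[str]:
    """Constitutional parts of a concept (its partonomy children), direct or
    as a transitive closure; sorted for deterministic output."""
    graph._require(concept_id)
    direct = graph.targets(concept_id, "constitutional_part")
    if not transitive:
        return sorted(direct)
    seen: set[str] = set()
    frontier = list(direct)
    while frontier:
        cid = frontier.pop()
        if cid in seen:
            continue
        seen.add(cid)
        frontier.extend(graph.targets(cid, "constitutional_part") - seen)
    return sorted(seen)


def laterality_of(graph: ConceptGraph, concept_id: str) -> Optional[str]:
    """The left/right laterality of a body part, or None when unsided."""
    graph._require(concept_id)
    return graph.nodes[concept_id].laterality


def extract_module(graph: ConceptGraph, config: ExtractionConfig) -> ConceptGraph:
    """Extract a self-connected module around the seed concepts.

    Kept set: seeds + their is_a ancestors (upper hierarchy), expanded over
    whitelisted property edges for up to ``hop_limit`` hops, minus the
    removal list; then orphan cleanup to fixpoint — a non-seed node with no
    is_a or property edge to another kept node is dropped, repeatedly.
    The operation is idempotent and monotone in hop_limit.
    """
    for s in config.seeds:
        if s not in graph:
            raise UnknownConceptError(f"unknown seed concept {s!r}")

    keep: set[str] = set(config.seeds)
    for s in config.seeds:
        keep |= graph.ancestors(s)

    frontier = set(keep)
    for _ in range(config.hop_limit):
        nxt: set[str] = set()
        for cid in frontier:
            nxt |= graph.neighbors(cid, config.property_types)
        nxt -= keep
        if not nxt:
            break
        keep |= nxt
        frontier = nxt

    keep -= config.removal_list
    seeds_kept = config.seeds - config.removal_list

    def has_link(cid: str, kept: set[str]) -> bool:
        others = kept - {cid}
        if graph.parents(cid) & others or set(graph._isa.predecessors(cid)) & others:
            return True
        for u, v, _ in graph._props.edges(cid, keys=True):
            if (u if v == cid else v) in others:
                return True
        for u, v, _ in graph._props.in_edges(cid, keys=True):
            if u in others:
                return True
        return False

    changed = True
    while changed:
        changed = False
        for cid in sorted(keep - seeds_kept):
            if len(keep) > 1 and not has_link(cid, keep):
                keep.discard(cid)
                changed = True

    return graph.subgraph(keep)
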