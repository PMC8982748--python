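"""Toy terminology graph and the path-measure similarity.

The graph holds concept nodes (with preferred terms), a many-to-one map
from normalized surface terms to concepts (so "structure of heart" and
"cardiac" can share one concept), and is-a edges.  Similarity between two
terms is the path measure

    sim(c_i, c_j) = 1 / l(c_i, c_j)

where ``l`` counts the *nodes* on the shortest path between the two
mapped concepts, endpoints included: identical concepts give l = 1 and
sim = 1; a parent and child give l = 2 and sim = 1/2.  If either term is
unmappable, or the mapped concepts live in different components, the
similarity is the sentinel −1.  Returned scores therefore always lie in
(0, 1] ∪ {−1}; 0 is unreachable.

Edges are traversed undirected — the hierarchy is climbed both up and
down, as the standard path measure does.  The file format is a plain
UTF-8 TSV with three record kinds::

    CONCEPT <id> <preferred term>
    ISA     <child id> <parent id>
    TERM    <surface term> <id>

No licensed vocabulary is required; a real terminology can be exported
into this format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .annotations import normalize_term

__all__ = ["TerminologyGraph", "UNMAPPABLE", "load_terminology", "save_terminology"]

#: Sentinel similarity for unmappable or disconnected term pairs.
UNMAPPABLE = -1.0


class TerminologyError(ValueError):
    """Malformed terminology file or lookup of an undeclared concept."""


@dataclass
class TerminologyGraph:
    """Concept nodes + surface-term map + undirected is-a links."""

    preferred_terms: dict[str, str] = field(default_factory=dict)
    term_map: dict[str, str] = field(default_factory=dict)
    _graph: nx.Graph = field(default_factory=nx.Graph)

    def add_concept(self, concept_id: str, preferred_term: str) -> None:
        self.preferred_terms[concept_id] = preferred_term
        self._graph.add_node(concept_id)
        self.add_term(preferred_term, concept_id)

    def add_edge(self, child: str, parent: str) -> None:
        for endpoint in (child, parent):
            if endpoint not in self.preferred_terms:
                raise TerminologyError(f"edge endpoint {endpoint!r} is not a declared concept")
        self._graph.add_edge(child, parent)

    def add_term(self, surface_term: str, concept_id: str) -> None:
        if concept_id not in self.preferred_terms:
            raise TerminologyError(f"term target {concept_id!r} is not a declared concept")
        self.term_map[normalize_term(surface_term)] = concept_id

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    # -- lookups ---------------------------------------------------------

    def map_term(self, term: str) -> str | None:
        """Exact-string lookup of a normalized surface term; None if unknown."""
        return self.term_map.get(normalize_term(term))

    def path_length(self, a: str, b: str) -> int | None:
        """Number of nodes on the shortest path between concepts, endpoints
        included; 1 when ``a == b``; None when no path exists."""
        for c in (a, b):
            if c not in self.preferred_terms:
                raise TerminologyError(f"undeclared concept {c!r}")
        if a == b:
            return 1
        try:
            return nx.shortest_path_length(self._graph, a, b) + 1
        except nx.NetworkXNoPath:
            return None

    def path_similarity(self, term_a: str, term_b: str) -> float:
        """Path-measure similarity of two surface terms; −1 when either
        term is unmapped or the concepts are disconnected."""
        ca = self.map_term(term_a)
        cb = self.map_term(term_b)
        if ca is None or cb is None:
            return UNMAPPABLE
        length = self.path_length(ca, cb)
        if length is None:
            return UNMAPPABLE
        return 1.0 / length

    def similarity_row(self, term: str, candidates: list[str]) -> dict[str, float]:
        """Similarities of one term against many candidate terms.

        Equivalent to calling :meth:`path_similarity` per pair but uses a
        single breadth-first sweep from the source concept, which matters
        when one outside-record concept is compared against a whole
        note-corpus vocabulary.
        """
        source = self.map_term(term)
        if source is None:
            return {c: UNMAPPABLE for c in candidates}
        dist = nx.single_source_shortest_path_length(self._graph, source)
        out: dict[str, float] = {}
        for cand in candidates:
            node = self.map_term(cand)
            if node is None or node not in dist:
                out[cand] = UNMAPPABLE
            else:
                out[cand] = 1.0 / (dist[node] + 1)
        return out


def load_terminology(path: str | Path) -> TerminologyGraph:
    graph = TerminologyGraph()
    edges: list[tuple[str, str]] = []
    terms: list[tuple[str, str]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            if kind == "CONCEPT" and len(parts) == 3:
                graph.add_concept(parts[1], parts[2])
            elif kind == "ISA" and len(parts) == 3:
                edges.append((parts[1], parts[2]))
            elif kind == "TERM" and len(parts) == 3:
                terms.append((parts[1], parts[2]))
            else:
                raise TerminologyError(f"{path}:{lineno}: malformed line {line!r}")
    for child, parent in edges:
        graph.add_edge(child, parent)
    for surface, cid in terms:
        graph.add_term(surface, cid)
    return graph


def save_terminology(graph: TerminologyGraph, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for cid in sorted(graph.preferred_terms):
            fh.write(f"CONCEPT\t{cid}\t{graph.preferred_terms[cid]}\n")
        for child, parent in sorted(graph.graph.edges()):
            fh.write(f"ISA\t{child}\t{parent}\n")
        for surface in sorted(graph.term_map):
            fh.write(f"TERM\t{surface}\t{graph.term_map[surface]}\n")
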