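"""Core in-memory containers for directed pathway networks and their inputs.

A pathway is modelled as a simple directed graph over opaque protein
identifiers: no duplicate directed edges, self-loops permitted, and an
antiparallel pair (a->b and b->a) counts as two distinct edges.  Isolated
nodes are representable (they arise naturally from node-deletion
experiments and can be declared via node-list sidecars on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import networkx as nx

Edge = Tuple[str, str]


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple digraph over protein identifiers.

    Parameters
    ----------
    nodes
        All node identifiers, including isolated ones.
    edges
        Directed edges as ``(source, target)`` pairs.  Every endpoint must
        be a member of ``nodes``.
    """

    nodes: FrozenSet[str]
    edges: FrozenSet[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()
    ) -> "DirectedNetwork":
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        nodes = frozenset(str(n) for n in extra_nodes) | frozenset(
            n for e in edge_set for n in e
        )
        return cls(nodes=nodes, edges=edge_set)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def transpose(self) -> "DirectedNetwork":
        """Network with every edge reversed."""
        return DirectedNetwork(self.nodes, frozenset((v, u) for u, v in self.edges))

    def remove_node(self, node: str) -> "DirectedNetwork":
        """Delete ``node`` and all incident edges, keeping all other nodes
        (nodes thereby isolated remain in the node set)."""
        if node not in self.nodes:
            raise KeyError(f"node {node!r} not in network")
        return DirectedNetwork(
            self.nodes - {node},
            frozenset(e for e in self.edges if node not in e),
        )

    def degree(self, node: str) -> int:
        """Total degree: in-degree + out-degree (a self-loop counts twice)."""
        return sum((u == node) + (v == node) for u, v in self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        return cls(frozenset(map(str, g.nodes)), frozenset((str(u), str(v)) for u, v in g.edges))


@dataclass
class PathwayCollection:
    """An ordered mapping from pathway identifier to its directed network."""

    pathways: Dict[str, DirectedNetwork]

    def __post_init__(self) -> None:
        if len(set(self.pathways)) != len(self.pathways):
            raise ValueError("pathway identifiers must be unique")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def __getitem__(self, key: str) -> DirectedNetwork:
        return self.pathways[key]

    @property
    def all_proteins(self) -> Set[str]:
        out: Set[str] = set()
        for net in self.pathways.values():
            out |= net.nodes
        return out


@dataclass(frozen=True)
class AnnotationSet:
    """A named set of proteins sharing a characteristic (e.g. essentiality)."""

    name: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation set {self.name!r} is empty")

    def restrict(self, universe: Iterable[str]) -> FrozenSet[str]:
        return self.members & frozenset(universe)


@dataclass
class OrthologyMap:
    """Many-to-many ortholog mappings between organism and human proteins.

    ``pairs`` maps an organism label to the set of
    ``(organism_protein, human_protein)`` pairs for that organism.
    """

    pairs: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)

    def add(self, organism: str, organism_protein: str, human_protein: str) -> None:
        self.pairs.setdefault(organism, set()).add((organism_protein, human_protein))

    @property
    def organisms(self) -> Set[str]:
        return set(self.pairs)

    def orthologs_of_human(self, organism: str, human_protein: str) -> Set[str]:
        return {o for o, h in self.pairs.get(organism, ()) if h == human_protein}

    def humans_of_ortholog(self, organism: str, organism_protein: str) -> Set[str]:
        return {h for o, h in self.pairs.get(organism, ()) if o == organism_protein}

    def human_to_orthologs(self, organism: str) -> Dict[str, Set[str]]:
        """Forward lookup table human protein -> set of organism orthologs."""
        table: Dict[str, Set[str]] = {}
        for o, h in self.pairs.get(organism, ()):
            table.setdefault(h, set()).add(o)
        return table
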