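"""Structural controllability of directed networks via maximum matching.

A directed network with linear dynamics can be fully controlled by
injecting signals into a minimum set of *driver nodes*.  That set is found
by mapping the digraph to a bipartite graph — each node v splits into an
out-copy v+ and an in-copy v-, each edge u->v becomes (u+, v-) — and
computing a maximum-cardinality matching M (Hopcroft-Karp).  Nodes whose
in-copy is unmatched are driver nodes; their minimum number is

    N_D = max(N - |M|, 1),

with the conventional floor of one driver for perfectly matched networks.

The importance of individual nodes is assessed by a deletion heuristic:
remove the node (keeping the rest of the node set, including nodes thereby
isolated), recompute the driver count N'_D over the remaining N-1 nodes,
and classify

    indispensable  (a *control node*)  if N'_D > N_D,
    neutral                            if N'_D = N_D,
    dispensable                        if N'_D < N_D.

Only the matching *cardinality* enters any result, and that cardinality is
unique, so the classification does not depend on which maximum matching
the algorithm happens to find.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Tuple

import networkx as nx
from networkx.algorithms.bipartite import hopcroft_karp_matching

from .network import DirectedNetwork, Edge

INDISPENSABLE = "indispensable"
NEUTRAL = "neutral"
DISPENSABLE = "dispensable"

_OUT = 0  # partition tags for bipartite copies
_IN = 1


@dataclass(frozen=True)
class MatchingResult:
    """A maximum matching and the driver-node set it implies."""

    matched_edges: FrozenSet[Edge]
    n_d: int
    driver_nodes: FrozenSet[str]

    @property
    def cardinality(self) -> int:
        return len(self.matched_edges)


@dataclass(frozen=True)
class NodeClassification:
    """Per-node deletion labels and the driver counts behind them."""

    labels: Dict[str, str]
    n_d_removed: Dict[str, int]
    n_d_intact: int
    n_nodes: int

    def nodes_with_label(self, label: str) -> FrozenSet[str]:
        return frozenset(n for n, lab in self.labels.items() if lab == label)

    @property
    def control_nodes(self) -> FrozenSet[str]:
        return self.nodes_with_label(INDISPENSABLE)


def to_bipartite(network: DirectedNetwork) -> nx.Graph:
    """Bipartite out-copy/in-copy mapping of a digraph.

    Node v yields vertices ``(_OUT, v)`` and ``(_IN, v)``; edge u->v yields
    the undirected bipartite edge ``((_OUT, u), (_IN, v))``.  A self-loop
    v->v yields ``((_OUT, v), (_IN, v))``.
    """
    bip = nx.Graph()
    for v in network.nodes:
        bip.add_node((_OUT, v), bipartite=0)
        bip.add_node((_IN, v), bipartite=1)
    for u, v in network.edges:
        bip.add_edge((_OUT, u), (_IN, v))
    return bip


def _match(bip: nx.Graph, top_nodes) -> Dict:
    """Maximum matching of the bipartite graph (Hopcroft-Karp)."""
    return hopcroft_karp_matching(bip, top_nodes=top_nodes)


def _floor(raw_driver_count: int) -> int:
    return max(raw_driver_count, 1)


def maximum_matching(network: DirectedNetwork) -> MatchingResult:
    """Maximum matching, driver nodes and minimum driver count N_D.

    The matched edge set may differ between runs or library versions;
    its cardinality — and hence ``n_d`` and ``len(driver_nodes)`` — is
    the unique quantity all downstream classification relies on.
    """
    bip = to_bipartite(network)
    top = [n for n in bip.nodes if n[0] == _OUT]
    matching = _match(bip, top)
    matched_edges = frozenset(
        (u[1], v[1]) for u, v in matching.items() if u[0] == _OUT and v[0] == _IN
    )
    matched_in = {v for _, v in matched_edges}
    drivers = frozenset(network.nodes - matched_in)
    return MatchingResult(
        matched_edges=matched_edges,
        n_d=_floor(network.n_nodes - len(matched_edges)),
        driver_nodes=drivers,
    )


def _n_d_without(bip: nx.Graph, n_nodes: int, node: str) -> int:
    """Driver count after deleting ``node``: restrict the bipartite graph
    (drop the node's out- and in-copy with their incident edges) and
    re-match over the remaining N-1 nodes."""
    view = nx.restricted_view(bip, [(_OUT, node), (_IN, node)], [])
    top = [n for n in view.nodes if n[0] == _OUT]
    matching = _match(view, top)
    cardinality = sum(1 for u in matching if u[0] == _OUT)
    return _floor((n_nodes - 1) - cardinality)


def _label(n_d_removed: int, n_d_intact: int) -> str:
    if n_d_removed > n_d_intact:
        return INDISPENSABLE
    if n_d_removed == n_d_intact:
        return NEUTRAL
    return DISPENSABLE


def classify_node(
    network: DirectedNetwork, node: str, n_d_intact: int | None = None
) -> str:
    """Deletion label of a single node (see module docstring for the rule)."""
    if node not in network.nodes:
        raise KeyError(f"node {node!r} not in network")
    if n_d_intact is None:
        n_d_intact = maximum_matching(network).n_d
    bip = to_bipartite(network)
    return _label(_n_d_without(bip, network.n_nodes, node), n_d_intact)


def _augment_from_out(
    start: int, banned, adj, match_out, match_in
) -> bool:
    """BFS for an augmenting path from the free out-copy ``start``,
    avoiding the in-copies in ``banned``; applies the augmentation if found."""
    parent_in = {}
    queue = [start]
    seen_out = {start}
    for u in queue:
        for v in adj[u]:
            if v in banned or v in parent_in:
                continue
            parent_in[v] = u
            w = match_in[v]
            if w == -1:  # free in-copy reached: flip the path
                while True:
                    u2 = parent_in[v]
                    prev = match_out[u2]
                    match_out[u2] = v
                    match_in[v] = u2
                    if prev == -1:
                        return True
                    v = prev
            if w not in seen_out:
                seen_out.add(w)
                queue.append(w)
    return False


def _augment_from_in(
    start: int, banned: int, radj, match_out, match_in
) -> bool:
    """Mirror search from the free in-copy ``start`` back to a free out-copy."""
    parent_out = {}
    queue = [start]
    seen_in = {start}
    for v in queue:
        for u in radj[v]:
            if u == banned or u in parent_out:
                continue
            parent_out[u] = v
            w = match_out[u]
            if w == -1:
                while True:
                    v2 = parent_out[u]
                    prev = match_in[v2]
                    match_in[v2] = u
                    match_out[u] = v2
                    if prev == -1:
                        return True
                    u = prev
            if w not in seen_in:
                seen_in.add(w)
                queue.append(w)
    return False


def classify_all(network: DirectedNetwork) -> NodeClassification:
    """Classify every node by the deletion heuristic against the intact N_D.

    The intact maximum matching is computed once; each deletion drops the
    node's out- and in-copy from it and restores maximality with at most
    two augmenting-path searches.  (No augmenting path avoiding the
    deleted node existed beforehand, so any new one must start or end at
    one of the two partners the deletion freed.)  Results are identical to
    naive per-node copy-and-delete, and deterministic because only
    matching cardinalities enter.
    """
    if not network.nodes:
        raise ValueError("cannot classify an empty network")
    names = sorted(network.nodes)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    adj = [[] for _ in range(n)]
    radj = [[] for _ in range(n)]
    for u, v in sorted(network.edges):
        adj[index[u]].append(index[v])
        radj[index[v]].append(index[u])

    intact = maximum_matching(network)
    cardinality = intact.cardinality
    n_d_intact = intact.n_d
    match_out = [-1] * n
    match_in = [-1] * n
    for u, v in intact.matched_edges:
        match_out[index[u]] = index[v]
        match_in[index[v]] = index[u]

    n_d_removed: Dict[str, int] = {}
    labels: Dict[str, str] = {}
    for w, name in enumerate(names):
        mo = match_out[w]  # in-copy matched to w's out-copy
        mi = match_in[w]   # out-copy matched to w's in-copy
        saved_out = match_out.copy()
        saved_in = match_in.copy()
        card = cardinality
        if mo == w:  # matched self-loop: one edge covers both copies,
            # and its removal frees no partner outside w
            match_out[w] = -1
            match_in[w] = -1
            card -= 1
            mo = mi = -1
        else:
            if mo != -1:
                match_out[w] = -1
                match_in[mo] = -1
                card -= 1
            if mi != -1:
                match_in[w] = -1
                match_out[mi] = -1
                card -= 1
        # Any augmenting path avoiding w must start at the freed out-copy
        # mi or end at the freed in-copy mo (else it would have augmented
        # the intact matching).  The first search bans mo so that a
        # mi -> ... -> mo path is left for the second, which also covers
        # the case of two vertex-disjoint augmenting paths.
        if mi != -1 and mi != w:
            if _augment_from_out(mi, (w, mo), adj, match_out, match_in):
                card += 1
        if mo != -1 and mo != w:
            if _augment_from_in(mo, w, radj, match_out, match_in):
                card += 1
        nd = _floor((n - 1) - card)
        n_d_removed[name] = nd
        labels[name] = _label(nd, n_d_intact)
        match_out = saved_out
        match_in = saved_in

    return NodeClassification(
        labels=labels,
        n_d_removed=n_d_removed,
        n_d_intact=n_d_intact,
        n_nodes=n,
    )


def control_nodes(network: DirectedNetwork) -> FrozenSet[str]:
    """The indispensable (control) nodes of a network."""
    return classify_all(network).control_nodes
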