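"""Synthetic pathway collections, annotation sets and organism copies.

The generators emulate the structural features the analysis depends on:
collections of small directed networks with overlapping node sets
(pathway crosstalk via shared "hub" proteins), heavy-tailed out-degree
structure, annotation sets with a tunable planted overlap with any target
group, and organism-specific copies with tunable rewiring and ortholog
coverage.  Hubs are spliced into pathways as mid-path relays (an edge
x->y becomes x->hub, hub->y) rather than appended as sources or sinks,
which tends to make them indispensable — so the planted
"multi-pathway controller" signal is structural, not assumed.

All generators are bit-deterministic under a fixed seed, and every
generator returns the ground truth needed to assert its planted signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import numpy as np

from ._seeds import derive_seed, rng_from
from .network import (
    AnnotationSet,
    DirectedNetwork,
    OrthologyMap,
    PathwayCollection,
)
from .perturbation import rewire_edges


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic pathway collection.

    ``edge_density`` is the mean number of directed edges per node;
    ``hub_insertion`` is the probability that each shared hub is spliced
    into a given pathway as a mid-path relay.
    """

    n_pathways: int = 50
    pathway_size_range: Tuple[int, int] = (10, 30)
    edge_density: float = 1.5
    n_shared_hubs: int = 2
    hub_insertion: float = 0.5
    min_edges: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_pathways <= 0 or lo <= 0 or hi < lo:
            raise ValueError("counts must be positive and size range ordered")
        if not 0.0 <= self.hub_insertion <= 1.0:
            raise ValueError("hub_insertion must be a probability")
        if self.n_shared_hubs < 0 or self.edge_density <= 0:
            raise ValueError("n_shared_hubs >= 0 and edge_density > 0 required")


def gen_random_digraph(
    n_nodes: int,
    n_edges: int,
    model: str = "uniform",
    seed: int = 0,
    node_prefix: str = "n",
) -> DirectedNetwork:
    """A simple random digraph with exactly ``n_edges`` distinct edges.

    ``uniform`` samples ordered pairs (self-loops allowed) uniformly
    without replacement; ``powerlaw-out`` draws edge sources proportional
    to a heavy-tailed (rank ^ -1.5) weight sequence, giving a skewed
    out-degree distribution.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    max_edges = n_nodes * n_nodes  # ordered pairs including self-loops
    if n_edges < 0 or n_edges > max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}] for {n_nodes} nodes")
    names = [f"{node_prefix}{i}" for i in range(n_nodes)]
    rng = np.random.default_rng(seed)
    edges: Set[Tuple[str, str]] = set()
    if model == "uniform":
        codes = rng.choice(max_edges, size=n_edges, replace=False)
        edges = {(names[c // n_nodes], names[c % n_nodes]) for c in codes}
    elif model == "powerlaw-out":
        weights = (np.arange(1, n_nodes + 1)) ** -1.5
        weights /= weights.sum()
        budget = 100 * max(n_edges, 1) + 1000
        attempts = 0
        while len(edges) < n_edges and attempts < budget:
            attempts += 1
            src = int(rng.choice(n_nodes, p=weights))
            dst = int(rng.integers(n_nodes))
            edges.add((names[src], names[dst]))
        if len(edges) < n_edges:  # dense corner: fill uniformly
            remaining = [
                (names[i], names[j])
                for i in range(n_nodes)
                for j in range(n_nodes)
                if (names[i], names[j]) not in edges
            ]
            idx = rng.choice(len(remaining), size=n_edges - len(edges), replace=False)
            edges.update(remaining[i] for i in idx)
    else:
        raise ValueError(f"unknown model {model!r}")
    return DirectedNetwork.from_edges(edges, extra_nodes=names)


def _splice_hub(
    edges: Set[Tuple[str, str]], hub: str, rng: np.random.Generator
) -> bool:
    """Replace a random edge x->y by x->hub, hub->y; False if no edge admits it."""
    candidates = sorted(
        (x, y)
        for x, y in edges
        if hub not in (x, y) and (x, hub) not in edges and (hub, y) not in edges
    )
    if not candidates:
        return False
    x, y = candidates[rng.integers(len(candidates))]
    edges.discard((x, y))
    edges.add((x, hub))
    edges.add((hub, y))
    return True


def gen_pathway_collection(
    spec: SynthSpec,
) -> Tuple[PathwayCollection, Dict]:
    """A synthetic collection with crosstalk via spliced hub proteins.

    Each pathway gets its own namespaced node set plus any hubs spliced
    into it; the returned ground truth records hub identities and
    per-pathway membership.
    """
    hubs = [f"HUB{j}" for j in range(spec.n_shared_hubs)]
    lo, hi = spec.pathway_size_range
    pathways: Dict[str, DirectedNetwork] = {}
    hub_pathways: Dict[str, List[str]] = {h: [] for h in hubs}
    members: Dict[str, List[str]] = {}
    for p in range(spec.n_pathways):
        pid = f"pw{p:03d}"
        rng = rng_from(spec.seed, 1, p)
        size = int(rng.integers(lo, hi + 1))
        n_edges = min(max(spec.min_edges, round(spec.edge_density * size)), size * size)
        base = gen_random_digraph(
            size,
            n_edges,
            model="powerlaw-out",
            seed=derive_seed(spec.seed, 2, p),
            node_prefix=f"{pid}_g",
        )
        edges = set(base.edges)
        nodes = set(base.nodes)
        for j, hub in enumerate(hubs):
            if rng.random() < spec.hub_insertion and _splice_hub(edges, hub, rng):
                nodes.add(hub)
                hub_pathways[hub].append(pid)
        pathways[pid] = DirectedNetwork(frozenset(nodes), frozenset(edges))
        members[pid] = sorted(nodes)
    truth = {
        "hubs": hubs,
        "hub_pathways": hub_pathways,
        "pathway_members": members,
        "spec": spec,
    }
    return PathwayCollection(pathways), truth


def gen_annotation(
    planted_in: Iterable[str],
    universe: Iterable[str],
    set_size: int,
    planted_fraction: float,
    seed: int = 0,
    name: str = "SYNTH",
) -> AnnotationSet:
    """An annotation set with a planted overlap with a target group.

    ceil(planted_fraction * set_size) members come from ``planted_in``;
    the remainder is drawn from the rest of the universe, all without
    replacement.
    """
    planted_in = sorted(set(planted_in))
    universe = sorted(set(universe))
    outside = sorted(set(universe) - set(planted_in))
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    n_planted = math.ceil(planted_fraction * set_size)
    if n_planted > len(planted_in):
        raise ValueError("not enough proteins in planted_in for the requested fraction")
    if set_size - n_planted > len(outside):
        raise ValueError("not enough proteins outside planted_in")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(planted_in, size=n_planted, replace=False)) if n_planted else []
    rest = set_size - n_planted
    if rest:
        chosen += list(rng.choice(outside, size=rest, replace=False))
    return AnnotationSet(name=name, members=frozenset(map(str, chosen)))


def gen_organism_copy(
    collection: PathwayCollection,
    rewire_fraction: float,
    ortholog_coverage: float,
    seed: int = 0,
    organism: str = "org",
) -> Tuple[PathwayCollection, OrthologyMap]:
    """An organism-specific copy of a collection with planted conservation.

    Every pathway is copied with node identifiers renamed into the
    organism's namespace (``organism:protein`` — the mapping is carried
    explicitly in the returned orthology table, never inferred from the
    prefix), then degree-preservingly rewired by ``rewire_fraction``.
    A uniformly chosen ``ortholog_coverage`` share of proteins receives
    1:1 ortholog entries.
    """
    if not 0.0 <= rewire_fraction <= 1.0 or not 0.0 <= ortholog_coverage <= 1.0:
        raise ValueError("proportions must be in [0, 1]")
    rename = {h: f"{organism}:{h}" for h in sorted(collection.all_proteins)}
    pathways: Dict[str, DirectedNetwork] = {}
    for i, (pid, net) in enumerate(collection):
        copied = DirectedNetwork(
            frozenset(rename[n] for n in net.nodes),
            frozenset((rename[u], rename[v]) for u, v in net.edges),
        )
        if rewire_fraction > 0:
            copied = rewire_edges(copied, rewire_fraction, derive_seed(seed, 3, i))
        pathways[pid] = copied
    humans = sorted(collection.all_proteins)
    rng = rng_from(seed, 4)
    n_covered = int(round(ortholog_coverage * len(humans)))
    covered = sorted(rng.choice(humans, size=n_covered, replace=False)) if n_covered else []
    omap = OrthologyMap()
    omap.pairs.setdefault(organism, set())
    for h in covered:
        omap.add(organism, rename[h], h)
    return PathwayCollection(pathways), omap
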