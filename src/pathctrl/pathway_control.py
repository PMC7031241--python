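"""Control profiling across a pathway collection.

Each pathway network is classified independently; a protein's *control
count* k is the number of pathways in which it is indispensable.  Because
pathways share proteins (crosstalk), a single protein can control many
pathways — the cumulative distribution of k is the collection-level
summary, and binning proteins by k defines the groups used in enrichment
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import pandas as pd

from .controllability import classify_all
from .network import PathwayCollection


@dataclass
class ControlProfile:
    """Per-protein pathway-control counts over a collection.

    ``counts`` covers every protein appearing in any pathway (count 0 for
    proteins that control none); ``pathway_controls`` maps each pathway to
    its indispensable set.
    """

    counts: Dict[str, int]
    pathway_controls: Dict[str, FrozenSet[str]]

    @property
    def controllers(self) -> Set[str]:
        return {p for p, c in self.counts.items() if c > 0}

    @property
    def max_count(self) -> int:
        return max(self.counts.values(), default=0)

    def proteins_controlling_at_least(self, k: int) -> Set[str]:
        return {p for p, c in self.counts.items() if c >= k}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["protein", "n_pathways_controlled"]
        )


@dataclass
class GroupBinning:
    """Disjoint half-open bins of proteins by pathway-control count."""

    bin_edges: List[int]
    groups: Dict[Tuple[int, int | None], Set[str]]

    def labels(self) -> List[str]:
        out = []
        for lo, hi in self.groups:
            out.append(f"[{lo},{hi})" if hi is not None else f">={lo}")
        return out


def profile_collection(collection: PathwayCollection) -> ControlProfile:
    """Classify every pathway independently and aggregate control counts."""
    if not len(collection):
        raise ValueError("cannot profile an empty collection")
    pathway_controls: Dict[str, FrozenSet[str]] = {}
    counts: Dict[str, int] = {}
    for pid, net in collection:
        controls = classify_all(net).control_nodes
        pathway_controls[pid] = controls
        for p in net.nodes:
            counts.setdefault(p, 0)
        for p in controls:
            counts[p] += 1
    return ControlProfile(counts=counts, pathway_controls=pathway_controls)


def cumulative_distribution(profile: ControlProfile) -> pd.DataFrame:
    """Table of (k, number of proteins controlling >= k pathways), k=1..max.

    The count column is non-increasing in k; an empty profile yields an
    empty table.
    """
    kmax = profile.max_count
    rows = [
        (k, sum(1 for c in profile.counts.values() if c >= k))
        for k in range(1, kmax + 1)
    ]
    return pd.DataFrame(rows, columns=["k", "n_proteins_ge_k"])


DEFAULT_BIN_EDGES = [1, 2, 3, 5, 10, 20]


def bin_by_control_count(
    profile: ControlProfile, bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> GroupBinning:
    """Assign each controlling protein to a half-open count bin.

    ``bin_edges`` [e1, e2, ..., em] defines bins [e1,e2), ..., [em, inf).
    Proteins with count below e1 (in particular count 0) fall in no bin.
    """
    edges = list(bin_edges)
    if not edges or any(e <= 0 for e in edges):
        raise ValueError("bin edges must be positive")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    intervals: List[Tuple[int, int | None]] = [
        (lo, hi) for lo, hi in zip(edges, edges[1:])
    ] + [(edges[-1], None)]
    groups: Dict[Tuple[int, int | None], Set[str]] = {iv: set() for iv in intervals}
    for protein, c in profile.counts.items():
        for lo, hi in intervals:
            if c >= lo and (hi is None or c < hi):
                groups[(lo, hi)].add(protein)
                break
    return GroupBinning(bin_edges=edges, groups=groups)
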