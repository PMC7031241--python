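"""Monte-Carlo log2 enrichment of annotation sets within protein groups.

For a group *i* of proteins and an annotation (characteristic) *A*, the
observed overlap N_i^A is compared with the overlap N_i^{r,A} obtained by
repeatedly resampling |A| proteins uniformly without replacement from the
universe.  The enrichment statistic is

    E_i^A = log2( N_i^A / mean_r N_i^{r,A} ),

positive when the annotation is over-represented in the group and
negative when diluted.  The same statistic applies cumulatively to the
groups of proteins controlling at least k pathways (E_{>=k}^A) and to
degree bins of a network.

The resampled overlap count is exactly hypergeometric(|universe|, |group|,
|A|), so null counts are drawn from that distribution directly — sample
for sample identical in law to drawing protein sets.  Null counts are
averaged before the single log is taken (the default); the alternative
``avg_order="logs"`` averages per-sample log-ratios with a +0.5
pseudocount, since individual null counts are frequently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .network import AnnotationSet, DirectedNetwork

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs resampled overlap of an annotation with a protein group."""

    group_label: str
    annotation_name: str
    n_observed: int
    null_mean: float
    e_value: float  # +/-inf when censored (zero observed or zero null mean)
    n_samples: int
    seed: int
    n_group: int
    n_annotation: int
    censored: bool = False


def _e_value(n_observed: int, null_counts: np.ndarray, avg_order: str) -> Tuple[float, float, bool]:
    null_mean = float(null_counts.mean())
    if avg_order == "logs":
        e = float(np.mean(np.log2((n_observed + 0.5) / (null_counts + 0.5))))
        return e, null_mean, False
    if n_observed == 0:
        return float("-inf"), null_mean, True
    if null_mean == 0.0:
        return float("inf"), null_mean, True
    return float(np.log2(n_observed / null_mean)), null_mean, False


def enrich_group(
    group: Iterable[str],
    annotation: AnnotationSet,
    universe: Iterable[str],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    group_label: str = "group",
    avg_order: str = "counts",
) -> EnrichmentResult:
    """Enrichment of ``annotation`` members within ``group``.

    ``group`` must be a nonempty subset of ``universe`` and the annotation
    must intersect the universe.  Each of the ``n_samples`` null draws
    resamples |annotation ∩ universe| proteins from the universe and
    counts the overlap with the group.
    """
    if avg_order not in ("counts", "logs"):
        raise ValueError(f"unknown avg_order {avg_order!r}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    group = frozenset(group)
    universe = frozenset(universe)
    if not group:
        raise ValueError("group is empty")
    if not group <= universe:
        raise ValueError("group must be a subset of the universe")
    ann_in_universe = annotation.restrict(universe)
    if not ann_in_universe:
        raise ValueError(
            f"annotation {annotation.name!r} does not intersect the universe"
        )
    n_observed = len(group & ann_in_universe)
    rng = np.random.default_rng(seed)
    # overlap of a uniform without-replacement draw with the group is
    # hypergeometric(|U|, |group|, |A|)
    null_counts = rng.hypergeometric(
        ngood=len(group),
        nbad=len(universe) - len(group),
        nsample=len(ann_in_universe),
        size=n_samples,
    )
    e, null_mean, censored = _e_value(n_observed, null_counts, avg_order)
    return EnrichmentResult(
        group_label=group_label,
        annotation_name=annotation.name,
        n_observed=n_observed,
        null_mean=null_mean,
        e_value=e,
        n_samples=n_samples,
        seed=seed,
        n_group=len(group),
        n_annotation=len(ann_in_universe),
        censored=censored,
    )


def enrich_cumulative(
    profile,
    annotation: AnnotationSet,
    universe: Iterable[str],
    k_values: Sequence[int],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    avg_order: str = "counts",
) -> List[EnrichmentResult]:
    """E_{>=k}: enrichment in groups of proteins controlling >= k pathways.

    ``profile`` is a :class:`~pathctrl.pathway_control.ControlProfile`.
    k values beyond the maximum control count yield empty groups and are
    skipped with a warning.
    """
    ks = list(k_values)
    if any(k <= 0 for k in ks) or any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("k_values must be positive and ascending")
    universe = frozenset(universe)
    results: List[EnrichmentResult] = []
    for i, k in enumerate(ks):
        group = frozenset(profile.proteins_controlling_at_least(k)) & universe
        if not group:
            logger.warning("no proteins control >= %d pathways; k=%d skipped", k, k)
            continue
        results.append(
            enrich_group(
                group,
                annotation,
                universe,
                n_samples=n_samples,
                seed=derive_seed(seed, i),
                group_label=f">={k}",
                avg_order=avg_order,
            )
        )
    return results


def enrich_degree_bins(
    network: DirectedNetwork,
    target: Iterable[str],
    bin_edges: Sequence[int],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    avg_order: str = "counts",
) -> List[EnrichmentResult]:
    """Enrichment of ``target`` proteins across total-degree bins.

    Nodes are binned by in-degree + out-degree into half-open intervals
    [e_i, e_{i+1}) with a final open-ended [e_m, inf) bin; the target set
    acts as the annotation and the network's nodes as the universe.
    Empty bins are skipped.
    """
    target = frozenset(target)
    if not target <= network.nodes:
        raise ValueError("target must be a subset of the network's nodes")
    edges = list(bin_edges)
    if any(e < 0 for e in edges) or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be non-negative and strictly ascending")
    degree = {n: network.degree(n) for n in network.nodes}
    intervals: List[Tuple[int, Optional[int]]] = [
        (lo, hi) for lo, hi in zip(edges, edges[1:])
    ] + [(edges[-1], None)]
    annotation = AnnotationSet(name="target", members=target)
    results: List[EnrichmentResult] = []
    for i, (lo, hi) in enumerate(intervals):
        members = frozenset(
            n for n, d in degree.items() if d >= lo and (hi is None or d < hi)
        )
        if not members:
            continue
        label = f"[{lo},{hi})" if hi is not None else f">={lo}"
        results.append(
            enrich_group(
                members,
                annotation,
                network.nodes,
                n_samples=n_samples,
                seed=derive_seed(seed, i),
                group_label=label,
                avg_order=avg_order,
            )
        )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "group": r.group_label,
            "annotation": r.annotation_name,
            "n_group": r.n_group,
            "n_annotation": r.n_annotation,
            "n_observed": r.n_observed,
            "null_mean": r.null_mean,
            "e_value": r.e_value,
            "censored": r.censored,
            "n_samples": r.n_samples,
            "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
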