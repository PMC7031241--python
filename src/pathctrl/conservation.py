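"""Cross-organism conservation of control.

Human control proteins are mapped through an explicit orthology table to
another organism; a human protein counts as a *conserved control* if any
of its orthologs is a control protein in the organism's network.  The
association between being a human control protein and being conserved as
a control is tested with a two-sided Fisher's exact test on the 2x2
contingency table, and the per-protein pathway-control counts of the two
organisms are correlated (Spearman by default — control counts are
heavy-tailed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
from scipy import stats

from .network import OrthologyMap

logger = logging.getLogger(__name__)

CONSERVED_CONTROL = "conserved_control"
CONSERVED_NONCONTROL = "conserved_noncontrol"
NO_ORTHOLOG = "no_ortholog"


@dataclass(frozen=True)
class ConservationResult:
    """Fisher's exact association between human and organism control sets.

    ``contingency`` rows are (human control, human non-control), columns
    (conserved as control, not conserved as control).
    """

    organism: str
    contingency: Tuple[Tuple[int, int], Tuple[int, int]]
    fisher_p: float
    odds_ratio: float
    n_mapped: int


def conserved_control_labels(
    human_universe: Iterable[str],
    organism_controls: Iterable[str],
    orthology: OrthologyMap,
    organism: str,
) -> Dict[str, str]:
    """Label every human protein by the control status of its orthologs.

    ``conserved_control`` if any ortholog is an organism control protein,
    ``conserved_noncontrol`` if it has orthologs but none is, and
    ``no_ortholog`` otherwise.
    """
    if organism not in orthology.organisms:
        raise KeyError(f"organism {organism!r} not present in the orthology map")
    organism_controls = frozenset(organism_controls)
    forward = orthology.human_to_orthologs(organism)
    labels: Dict[str, str] = {}
    for h in human_universe:
        orthologs = forward.get(h, set())
        if not orthologs:
            labels[h] = NO_ORTHOLOG
        elif orthologs & organism_controls:
            labels[h] = CONSERVED_CONTROL
        else:
            labels[h] = CONSERVED_NONCONTROL
    return labels


def conservation_test(
    human_controls: Iterable[str],
    labels: Mapping[str, str],
    restrict_to_mapped: bool = True,
    organism: str = "",
) -> ConservationResult:
    """Two-sided Fisher's exact test for conservation of control.

    By default only ortholog-mapped proteins enter the table; with
    ``restrict_to_mapped=False`` unmapped proteins count as not conserved.
    A table with any zero margin carries no information; its p-value is
    reported as 1 with a warning.
    """
    if not labels:
        raise ValueError("labels are empty")
    human_controls = frozenset(human_controls)
    if restrict_to_mapped:
        evaluated = [h for h, lab in labels.items() if lab != NO_ORTHOLOG]
    else:
        evaluated = list(labels)
    n_mapped = sum(1 for lab in labels.values() if lab != NO_ORTHOLOG)
    a = b = c = d = 0
    for h in evaluated:
        is_control = h in human_controls
        is_conserved = labels[h] == CONSERVED_CONTROL
        if is_control and is_conserved:
            a += 1
        elif is_control:
            b += 1
        elif is_conserved:
            c += 1
        else:
            d += 1
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0 or not evaluated:
        logger.warning("degenerate contingency table %s; p reported as 1", table)
        p = 1.0
        odds = float("nan")
    else:
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ConservationResult(
        organism=organism,
        contingency=table,
        fisher_p=float(p),
        odds_ratio=float(odds),
        n_mapped=n_mapped,
    )


def control_count_correlation(
    human_profile,
    organism_profile,
    orthology: OrthologyMap,
    organism: str,
    method: str = "spearman",
) -> Tuple[float, float]:
    """Correlation of pathway-control counts between organisms.

    Pairs (human count, max over orthologs of the organism count) are
    formed for every human protein with at least one ortholog.  Returns
    (coefficient, p-value); (NaN, NaN) with fewer than 3 pairs or zero
    variance on either side.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    forward = orthology.human_to_orthologs(organism)
    xs, ys = [], []
    for h, human_count in sorted(human_profile.counts.items()):
        orthologs = forward.get(h, set())
        if not orthologs:
            continue
        xs.append(human_count)
        ys.append(max(organism_profile.counts.get(o, 0) for o in orthologs))
    if len(xs) < 3 or len(set(xs)) < 2 or len(set(ys)) < 2:
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = stats.spearmanr(xs, ys)
    else:
        rho, p = stats.pearsonr(xs, ys)
    return float(rho), float(p)
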