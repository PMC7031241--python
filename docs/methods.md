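# Methods

## Controllability model

Pathways are treated as simple directed graphs over opaque protein
identifiers: duplicate directed records collapse, undirected records are
dropped at parse time (the controllability machinery is defined on
directed interactions only, and symmetrising would fabricate direction
information), self-loops are retained, and antiparallel pairs count as
two edges. Isolated nodes are representable; edge-list inputs cannot
express them, so an optional node-list sidecar may declare them, and node
deletion during classification keeps the remaining node set including
nodes the deletion isolates.

The driver-node set of a network with N nodes is obtained from a maximum
matching M of the bipartite out-copy/in-copy mapping, computed with
networkx's Hopcroft–Karp implementation. We adopt the conventional floor
N_D = max(N − |M|, 1): a perfectly matched network still needs one input.
The floor is applied on both sides of every classification comparison
(N′_D is floored over the N−1 remaining nodes), which only matters for
(near-)perfectly matched networks.

### Deletion heuristic and its implementation

Each node's label (indispensable / neutral / dispensable) compares N′_D
after deleting the node against the intact N_D. Naively this is one full
matching per node. Instead, the intact maximum matching is computed once;
deleting node w removes at most two matched edges (one if the matched
edge is w's self-loop), and maximality is restored with at most two
augmenting-path searches. This is complete because an augmenting path
avoiding w whose endpoints were already free would have augmented the
intact matching; every new augmenting path therefore starts at the
out-copy freed by w's deletion or ends at the freed in-copy. The first
search bans the freed in-copy so that a single path connecting the two
freed copies — and the case of two vertex-disjoint paths — are both
resolved by the dedicated second search. The implementation is asserted
equivalent to naive copy-and-delete re-matching in the test suite, on
random digraphs including self-loop cases.

Only matching cardinalities are ever compared, so results are independent
of node/edge iteration order and of which maximum matching the library
returns.

## Perturbations

*Flipping* reverses ⌈f·|E|⌉ edges drawn uniformly without replacement
from edges whose reversal does not collide with a current edge;
self-loops are never eligible (their reversal is the identity).
Collisions can make the achieved fraction fall short of the request; the
shortfall is reported, never silently ignored. On networks without
antiparallel pairs, f = 1 yields the exact transpose, whose
classification equals the original's (the transpose of a matching is a
matching of the transpose) — used as a built-in correctness endpoint in
the robustness sweeps.

*Rewiring* applies directed double-edge swaps (a→b, c→d → a→d, c→b),
rejecting swaps that would create self-loops or duplicates, until the
number of edges differing from the original edge set reaches ⌈f·|E|⌉ or
a budget of 100·|E| attempts is exhausted. Swaps preserve every node's
joint (in, out) degree — the stricter degree-preserving null. Because a
swap can also swap edges back, the chain's equilibrium overlap with the
original edge set is nonzero; for small heavy-tailed pathway graphs the
achieved changed fraction saturates near 0.7 regardless of budget (edges
out of a high-degree hub have high probability under the degree-preserving
ensemble and keep reappearing). The achieved fraction is always recorded.

The combined perturbation used for joint robustness composes
flip(0.5) then rewire(1.0) with independent derived sub-seeds; the order
is a documented convention.

## Enrichment statistic

E = log2(observed overlap / mean resampled overlap), with the null
resampling |A ∩ universe| proteins uniformly without replacement and
counting the overlap with the group; 10,000 samples by default. The
resampled count is exactly hypergeometric(|U|, |group|, |A|), so null
counts are drawn from that distribution directly — identical in law,
much faster. Null counts are averaged before the single log is taken;
the alternative of averaging per-sample logs is exposed
(`avg_order="logs"`, +0.5 pseudocount) because individual null counts
are frequently zero. Zero observed or zero null mean yields ±inf
sentinels flagged `censored` rather than pseudocounted values. The
sampling universe defaults to the proteins of the analysed collection or
network. No multiple-testing correction is applied; E is an effect size,
not a p-value.

Because E is a log of a ratio whose denominator is a Monte-Carlo mean,
its null expectation carries a Jensen bias of roughly −var/(2µ² ln 2)
where µ is the expected overlap; calibration checks therefore use group
and annotation sizes with µ ≈ 20 (universe 1,000, group 200, annotation
100), where the bias is ≈ 0.03 — far inside the ±0.1 calibration band.
With µ ≈ 5 the bias alone is ≈ 0.12, so small-overlap E values should be
read with that skew in mind.

## Conservation

A human protein is *conserved as control* if any of its orthologs is a
control protein in the organism network (any-ortholog rule for
many-to-many maps). The human-control × conserved-control association is
tested two-sided with `scipy.stats.fisher_exact` (checked against exact
hypergeometric enumeration for every 2×2 table with total ≤ 40);
degenerate margins report p = 1 with a warning. The contingency universe
defaults to ortholog-mapped proteins. Control-count correlation pairs
each mapped human protein's count with the maximum count over its
orthologs; Spearman is the default because counts are heavy-tailed.

## Synthetic data

The generator emulates the features the analysis depends on, not any
specific database snapshot:

- **Collections**: 50 pathways of 10–30 nodes (defaults), each a random
  digraph with heavy-tailed out-degree (sources drawn ∝ rank^−1.5) and a
  mean of 1.5 edges per node, min 5 edges. Shared hub proteins are
  spliced into pathways as mid-path relays (x→y becomes x→hub, hub→y)
  with probability 0.5 per pathway, because relays are the motif the
  deletion heuristic marks indispensable — the planted
  "multi-pathway controller" signal is structural, not assumed. The
  default of 2 hubs keeps crosstalk modest; analyses that need populated
  high-k groups (control-count enrichment, conservation) use 10 hubs so
  that the ≥2..≥5 groups hold ~10 proteins.
- **Annotations**: a set of chosen size with an exact planted overlap
  with any target group, remainder drawn outside it.
- **Organism copies**: per-pathway renamed copies (explicit 1:1 orthology
  entries for a chosen coverage share; the name prefix is cosmetic, the
  mapping is always carried explicitly) rewired by a chosen fraction.

What the generator does *not* emulate: curated interaction subtypes,
identifier ambiguity, database-version effects, many-to-many orthology,
and the empirical pathway-size and overlap distributions of real
databases. Passing tests therefore demonstrate the correctness and
calibration of the machinery, not the field-specific effect sizes of any
real pathway resource.

## Known limitations and honest negatives

Degree-preserving rewiring is *not* a control-destroying null: it keeps
every node's (in, out) degree, and indispensability is strongly
degree-associated. Consequently the per-protein control-count correlation
between a collection and its fully rewired copy plateaus around
ρ ≈ 0.3–0.45 (for both uniform and heavy-tailed generators and regardless
of swap budget), consistent with the observation that roughly half of all
control nodes survive complete rewiring. A test asserting ρ ≈ 0 after
full rewiring is retained and fails by design; treat full rewiring as a
wiring-identity null, not a degree null.

Seeds: every stochastic stage takes one integer seed; nested stages
derive child seeds from (master, counter path) via `SeedSequence`, so any
stage is reproducible in isolation from its recorded seed. Pipeline
outputs are byte-identical across runs at a fixed master seed.

Problem sizes in the shipped tests and acceptance script (collections of
50 pathways, pooled networks of ~10³ nodes, 10⁴ null samples, 2×10³
samples in multi-seed loops) were chosen as the smallest sizes at which
the planted signals are unambiguous.
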