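# Methods

## Input model and filtering

The pipeline consumes differential-expression *calls*, not counts: one
record per (gene, condition) with a log2 fold change and a BH-adjusted
p-value, as produced by any upstream DE tool. The ingest filter keeps
records with adj_p strictly below 0.05 and |log2 FC| of at least 1. The
strict/inclusive split follows the conventional reading of "p < 0.05"
and "|log FC| ≥ 1"; a record exactly at adj_p = 0.05 is excluded.
Direction is the sign of the fold change, per record, so a gene may
legitimately appear in the up-network for one condition and the
down-network for another. Identifiers are opaque case-sensitive strings;
no symbol or alias resolution is attempted.

## Bipartite centralities

The three measures use bipartite-specific normalizations so that scores
are comparable across graphs of different dimensions:

* degree is scaled by the opposite side's size (the maximum number of
  neighbors a node can have);
* closeness divides the minimum attainable distance sum — opposite-side
  nodes at distance 1, same-side nodes at distance 2 — by the observed
  BFS distance sum d_v. On a connected graph the score is 1 exactly when
  the node touches every opposite-side node; the formula does not bound
  scores by 1 in general and no such bound is asserted;
* betweenness divides the raw unordered-pair Brandes betweenness by a
  closed-form maximum that depends on both side sizes through the
  integer quotient/remainder pairs s,t = divmod(C_n−1, G_n) and
  p,r = divmod(G_n−1, C_n). "÷" and "mod" are floor division and modulo.

**Disconnected graphs.** Closeness is computed within each node's
component (unreachable pairs contribute nothing to d_v) while the
numerator keeps the global side sizes. This is a convention, documented
rather than derived: the flagship use case — a panel of conditions
sharing many genes — yields connected graphs, and isolated nodes score 0.

**Top-fraction selection.** Per measure, the top ceil(f·N) gene-side
nodes are selected (default f = 0.05) and every node tied with the
boundary score is included, which makes the selection deterministic
without arbitrary ordering among equals. The reported union also records
which measures selected each gene. Condition-side selection is available
via the `side` argument but is not the default, since the interesting
rankings are over genes.

## Configuration-model validation

The null preserves both degree sequences by uniform stub matching:
condition stubs are paired with a random permutation of gene stubs, then
parallel edges are collapsed so the null is simple like the real
network. Degrees are exact on the multigraph and deficient by the
collapsed multiplicity on the simple graph; per-node deficits are
reported. Replicate i uses seed `seed + i`, so a report is reproducible
from one master seed.

The test statistic is the node redundancy coefficient, computed for
every node of degree ≥ 2 on both sides (degree-<2 nodes, for which it is
undefined, are excluded and counted). The real distribution is compared
to each replicate's by the two-sample KS test (SciPy's exact D, with the
asymptotic p-value), and the decision compares the average D across
replicates (default 10) to D_crit = c(α)·√((n1+n2)/(n1·n2)), using the
tabulated Smirnov coefficients (c(0.05) = 1.36). Sample sizes are the
eligible-node counts of the two networks being compared; the report's
D_critical averages the per-replicate thresholds, which differ only
marginally through collapse-induced degree deficits.

**Power of the redundancy statistic.** Redundancy asks whether a node's
neighbor pairs are co-covered elsewhere. In a dense panel — few
conditions, many genes — almost every condition pair is co-covered by
*some* gene even in the null (expected co-coverage of a condition pair
scales like deg(c)·deg(c′)/G_n), so both distributions pile up near 1
and the test has little power against planted shared-profile modules.
The statistic separates real from null when co-occurrence is sparse:
many conditions relative to density, modules concentrated on few
condition pairs, and a background of narrow profiles. The structured
recovery experiment in the tests and acceptance script therefore uses a
40-condition, 600-gene configuration with 14 planted modules, sparse
background (breadth exponent 3.5) and no pan-module (a pan-module
co-covers every condition pair by itself and removes the signal); under
those conditions the verdict is `distinct` in ≥ 95% of seeds, while a
configuration-model draw validated against further draws is
`not-distinct` in the large majority of seeds.

## Projection, thresholding, components

The one-mode projection links same-side nodes with intersecting
neighborhoods, weighted by the Jaccard index of the neighborhood *sets*
(the bipartite graph is simple, so multiplicity never arises). w = 1
iff the neighborhoods are equal, so thresholding at 1.0 yields exactly
the identical-profile equivalence-class cliques. The edge threshold
(default 0.9) is inclusive (w ≥ cutoff), which keeps the exact-match
semantics stable at cutoff 1.0. Thresholding reports nodes left
isolated; `connected_components` partitions the edge-bearing nodes and
orders components by size, ties broken by smallest member. The cutoff
sweep counts components over the projection's full node set with
isolated nodes as singletons — on that fixed node set raising the
cutoff only removes edges, giving strict monotonicity (component count
non-decreasing, largest component non-increasing).

Component condition profiles report, per condition, the fraction of
component genes called in it, plus a hypergeometric enrichment with the
direction network's gene set as universe, BH-adjusted across
conditions; a component "characterizes" the conditions with adjusted
p < 0.05.

## Enrichment

All tests use the upper tail P(X ≥ k) (over-representation only) and
explicit universes — GRN target genes for TF enrichment, network genes
for condition profiles, a caller-supplied universe for gene sets —
because the appropriate background differs per question. The TF filter
cascade follows a fixed order: rank TFs by ascending adjusted p and
keep the top 25% (ceiling, boundary ties included), then require
adjusted p < 0.05, then require ≥ 10 targets inside the query. The
order matters and is deliberately not commutative with the count
filter. Edge-overlap significance between a thresholded projection and
a reference interactome restricts both edge sets to the shared nodes
and uses all unordered shared-node pairs as the universe (an
`all pairs over the union` variant exists for sensitivity analysis).

## Synthetic data

The generator emulates the shape of a multi-condition DEG compendium:

* **breadth** — background genes are called in k conditions with
  P(k) ∝ k^(−α) truncated to [1, n_conditions] (default α = 2), giving
  the observed pattern of many condition-specific genes and few broadly
  dysregulated ones; condition subsets are uniform given k;
* **modules** — each planted module shares one condition profile
  (breadth drawn from the same law restricted to ≥ 2) and one
  direction, so noise-free modules project to weight-1 cliques;
* **pan-module** — 43 genes (default) called in all conditions, the
  pan-condition motif, guaranteed to top the degree ranking at noise 0;
* **records** — |log2 FC| = 1 + Exp(1) with sign matching direction,
  adj_p uniform on (0, 0.05): the generator simulates post-filter
  calls, mirroring the hand-off from an upstream DE caller, and makes
  no attempt at a count model;
* **noise** — each (gene, condition) membership cell flips
  independently with rate 0.01 by default (0 in recovery experiments,
  which state so explicitly);
* **references** — the PPI contains each intra-module pair with
  probability `ppi_overlap_frac` plus |genes| random background pairs;
  each module gets a TF targeting it plus ~20% decoy targets,
  alongside random decoy TFs; the gene-set collection has one term per
  module plus random decoy terms.

Defaults (18 conditions, 5000 genes, 8 modules of 10–40 genes) are the
panel scale the pipeline is designed around. What passing recovery
tests show is that the pipeline's machinery is correct and sensitive to
the planted structure; they do not show that real compendia contain
such clean modules — real profiles are correlated across related
conditions, directions are not independent coin flips, and real
adjusted p-values are not uniform.

## Numerical choices

* File output at fixed 6-decimal precision; round-trips compare floats
  at 5e-7.
* Hypergeometric tails via `scipy.stats.hypergeom.sf`, which works in
  log space; BH via `statsmodels.stats.multitest.multipletests`.
* Boundary-tie comparisons in top-fraction selection use an absolute
  1e-12 tolerance.
* Seeds: `validate_against_null` derives replicate seeds as
  `seed + i`; the simulator derives its reference-resource stream from
  `[seed, 1]` so table and references are independently reproducible.

## Limitations

* Centralities, projection and redundancy are exact but not optimized
  for very large graphs (the projection's candidate-pair enumeration is
  quadratic in the largest condition degree); panels up to tens of
  thousands of genes are comfortable, whole-interactome projections are
  not the target.
* The redundancy-KS validation's power limitation in dense few-condition
  panels (above) is a property of the statistic, not of the
  implementation; alternative nulls (edge swaps) and statistics are out
  of scope.
* No community detection is bundled; components of the thresholded
  projection are the grouping primitive, and any clustering algorithm
  can be applied to the exported edge lists.
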