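# Methods

## Problem setting

Two comorbid diseases that share etiology tend to perturb overlapping
neighborhoods of the protein–protein interaction network (PPIN).  If
disease B has well-characterized drug targets and disease A has few, the
network modules shared by both diseases — and in particular their most
central genes — are rational candidate targets for A.  `ppdt` implements
this reasoning as a deterministic pipeline plus a synthetic study generator
with recorded ground truth.

## Module mining

**Seed neighborhoods.**  The disease's gene set seeds a breadth-first
k-step neighborhood (default k = 3) of the unweighted, simple PPIN; the
induced subgraph on all nodes within distance k is clustered.  Seeds absent
from the network are dropped with a warning; a completely absent seed set
is an error.

**Markov clustering.**  MCL is implemented directly on the dense adjacency
matrix: self-loops of weight 1 are added (canonical practice; prevents
oscillation on bipartite-like structures), columns are normalized, and the
iteration alternates expansion (matrix power, default 2) with inflation
(entrywise power, default 1.8, then column renormalization), pruning
entries below 1e-5 and renormalizing, until the largest entry change falls
below 1e-6 or 100 iterations (non-convergence returns the current state
with a warning).  Rows retaining mass are attractors; attractors attracted
to one another form one attractor system, and each system's nonzero
columns form a cluster.  A node claimed by several systems goes to the
largest cluster, ties broken lexicographically by the cluster's smallest
gene symbol, so the output is a deterministic partition.  Singleton
clusters are kept: downstream role filters remove useless modules
naturally, and no minimum number of seeds per cluster is required.

## Pairing and candidate modules

All cross-disease module pairs are scored with the Jaccard index.  The
retention threshold is the **median of the nonzero** J values (strictly
greater than): with many modules almost all pairs are disjoint, so a
median over all pairs degenerates to 0 and the threshold becomes vacuous;
`median_scope="all"` restores the literal all-pairs median.  A retained
pair's intersection becomes a candidate module only if it contains at
least one disease-A gene, one disease-B gene and one disease-B drug
target (a single gene may fill several roles).  Identical intersections
from different pairs collapse to one candidate.

## Centrality prioritization (G-rank)

Centralities are computed on the candidate module's induced subgraph
within the full input network, not on the whole network.  Degree is the
incident edge count; closeness the inverse mean geodesic distance to the
other n−1 genes; betweenness the fraction of all shortest paths passing
through the gene, with the standard undirected normalization (whether
ordered or unordered pairs are counted only changes a constant factor,
which cancels in ranking); PageRank uses uniform teleportation with
damping 0.85 (configurable) iterated to 1e-10.  Ranks per metric are
ordinal with lexicographic tie-breaks (a deterministic total order;
fractional mid-ranks are available behind `tie_policy="average"`).  The
G-rank is the ascending rank of the fourth root of the product of the four
per-metric ranks.  Because only ranks enter the aggregate, the G-rank is
invariant under any strictly monotone transformation of the raw values —
a property the test suite asserts.

Candidate modules are pair intersections, not MCL clusters, so their
induced subgraphs need not be connected; the pipeline therefore enables
the disconnected fallback (closeness over reachable genes only,
betweenness per component, PageRank on the whole graph).  The library
default remains an error on disconnected input.

## Enrichment and target selection

The query is (module genes ∪ disease-A genes) ∩ universe; the universe
defaults to the annotation catalog's own gene universe and can be widened
to the network's genes.  Each term is scored with the hypergeometric
**upper tail** P(X ≥ k) — the point probability alone is not a
significance measure — evaluated in log space.  BH-FDR is applied jointly
across all tested terms (BP, MF, pathway) per module; a term is
significant at q < 0.05.  A candidate is functionally consistent with
disease A when at least `min_terms` (default 1) significant terms are hit
by module genes *and* disease-A genes together.  Final targets are the
genes in the upper quartile of the G-rank — cutoff ceil(n/4), which maps
an 85-gene module to 22 targets — that also appear among the hits of at
least one significant term.

## Efficiency evaluation

One feature per gene (probe rows averaged), samples restricted to the
task's two statuses (normal vs disease; disease vs treated, the second
status being the positive class).  Per repeat, a stratified five-fold
split is drawn from sub-seed `seed + r`; per fold, features are z-scored
on the training data and a soft-margin linear SVM (C = 1) is fitted — the
smallest-assumption default for n ≪ p expression data; kernel and cost are
configurable.  Sensitivity, specificity, accuracy and MCC are computed at
the zero decision threshold on the repeat's pooled held-out predictions;
AUC from pooled held-out decision scores by Mann–Whitney pair counting
(equal to the trapezoidal area under the empirical ROC, asserted in
tests).  MCC is defined as 0 when a marginal factor vanishes.  Stratified
folds are used because with small unbalanced groups plain folds can turn
single-class; a degenerate training fold redraws the repeat from the next
sub-seed.  Disease/treated pairing is ignored during splitting — a known
leakage caveat, as fold membership of one pair member says nothing about
labels but does share subject-level noise.

**Consistency filter.**  Each sample is compared with the per-gene median
of the other samples of its status group by a two-sided Wilcoxon
signed-rank test, BH-corrected across samples; a sample is consistent iff
q ≥ 0.05.  The test is applied *sequentially*: the single most deviant
significant sample is removed from the reference pool and the rest are
re-tested until none is significant.  A single gross outlier shifts the
leave-one-out group median of every clean sample by a small but systematic
amount, which a signed-rank test across hundreds of genes reliably
detects; the sequential form isolates actual outliers instead of flagging
the whole group.  Consistent normal samples are kept; a disease/treated
pair is kept iff its treated member is consistent (treated samples that
reached the common post-treatment state define the usable pairs).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- **Network** (defaults: 8 planted modules × 20 genes, within-module edge
  probability 0.9, between-module 0.01): a planted-partition core plus a
  sparse periphery of ~70 background nodes in pendant/branching chains
  anchored on module genes (5% shortcut edges).  The periphery is what
  makes the two disease neighborhoods differ at their k-step frontiers;
  without it both subnetworks coincide at this scale, the two MCL
  partitions are identical, and every nonzero Jaccard value ties at
  exactly 1.0 — emptying the strict-median rule.
- **Gene sets** (defaults: 12 disease-A genes, 14 disease-B genes, 5
  targets, 1 shared module): module 1 is shared, modules 2–3 are
  A-specific, 4–5 B-specific; each disease set draws ≥2 genes from the
  shared module.  Targets are the shared module's most central members
  (top G-rank of its induced subgraph) — the premise being that drug
  targets sit at the module core.
- **Annotation**: one term per planted module (optionally jittered) plus
  20 noise terms of 10–30 random genes; universe = all network genes.
- **Expression** (defaults: 13 normal, 10 paired disease/treated samples,
  2 probes per gene): per-gene baseline ~ N(7, 1) on the log scale (no
  normalization stage is modeled), additive effect +2 on target genes in
  disease samples, full reversion in treated responders.  Half the treated
  samples are non-responders: they keep the disease state and drift by a
  ±1 global shift — a pure reversion failure on a handful of genes would
  be invisible to a whole-profile consistency test, so the shift is what
  gives the filter real work (mirroring a cohort where half the patients
  respond).

Every generator is a pure function of its parameters and seed.

What passing the synthetic tests does *not* show about real data: the
planted modules are denser and crisper than real pathway modules, probes
are exchangeable within genes (no platform artifacts, batch effects or
missing values), expression noise is i.i.d. Gaussian, and the periphery is
far smaller than a real PPIN's.  Dataset-dependent quantities (module
counts in the hundreds, specific classification averages) are therefore
out of reach at this scale by design.

## Numerical and design notes

- All file formats are plain TSV/GMT/text; symbols are uppercased and
  whitespace-trimmed on ingest; no alias resolution.
- Self-loops and duplicate or reversed edges are dropped with a logged
  count; readers are line-order independent.
- The hypergeometric tail, BH step-up, closeness/betweenness and AUC each
  have an independent test oracle (exhaustive draw enumeration, hand-coded
  step-up, BFS path enumeration, trapezoidal ROC).
- Null calibrations in the acceptance tests run at sizes where the
  discrete hypergeometric test's attainable level (0.041 at N = 2000,
  M = 200, n = 300) is close to nominal.
- Pipeline outputs are stamped with a SHA-256 hash of the configuration;
  reruns with the same configuration are byte-identical.

## Known limitations

- **Strict-median knife edge.**  When the two seed neighborhoods happen to
  coincide exactly, both partitions are identical, all nonzero Jaccard
  values equal 1.0, and the strictly-greater-than median rule retains
  nothing.  At the default synthetic scale this occurs for roughly 1 seed
  in 10; `median_scope="all"` is the robust alternative, and at realistic
  network scales the degeneracy is improbable.
- The consistency filter assumes deviant samples are a minority of their
  group; if most of a group drifts, the sequential removal can peel the
  wrong side.
- CV folds ignore subject pairing (see above).
- GO term redundancy/ancestor propagation is not modeled; enrichment
  treats terms as flat sets.
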