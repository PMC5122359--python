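"""Disease-module mining: seed neighborhoods and Markov clustering.

Disease genes seed a k-step neighborhood subnetwork of the full interaction
network (k = 3 by default), which is then partitioned into modules with the
Markov Cluster algorithm (MCL).  MCL simulates random-walk flow on the
graph, alternating *expansion* (matrix powers, spreading flow) and
*inflation* (entrywise powers, concentrating flow) until the process
converges on a set of attractor states; each attractor basin is a module.
The inflation parameter controls granularity (default 1.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ppdt.network_io import GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

_SOURCE_FOR_ROLE = {"disease_A": "A", "disease_B": "B"}


@dataclass(frozen=True)
class GeneModule:
    """A named gene set produced by clustering or module intersection."""

    id: str
    genes: frozenset[str]
    source: str  # A | B | intersection | custom

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering parameters.

    inflation > 1 sets granularity; expansion is the matrix-power step;
    entries below prune_threshold are zeroed each iteration; iteration stops
    when the largest entry change falls below tol or at max_iter.
    """

    inflation: float = 1.8
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")


def k_step_neighborhood(
    net: InteractionNetwork, seeds: GeneSet, k: int
) -> InteractionNetwork:
    """Induced subgraph on every node within unweighted distance k of a seed.

    Seeds absent from the network are dropped with a warning; if no seed is
    present the neighborhood is undefined and an error is raised.  k = 0
    returns the induced subgraph on the present seeds alone.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    present = seeds.genes & net.nodes
    absent = seeds.genes - net.nodes
    if absent:
        logger.warning(
            "%d of %d seed genes absent from the network", len(absent), len(seeds.genes)
        )
    if not present:
        raise ValueError(f"no seed of {seeds.name!r} is present in the network")
    reach: set[str] = set()
    for depth, layer in enumerate(nx.bfs_layers(net.graph, sorted(present))):
        if depth > k:
            break
        reach.update(layer)
    return net.induced(reach)


def _mcl_partition(
    A: np.ndarray, params: MCLParams
) -> tuple[list[set[int]], bool]:
    """Run MCL on an adjacency matrix; return clusters of indices + converged flag.

    Self-loops of weight 1 are added before column normalization (canonical
    practice; prevents oscillation on bipartite-like structures).  After
    convergence, rows retaining mass are attractors; overlapping attractor
    rows are merged into one attractor system and each system's nonzero
    columns form a cluster.
    """
    n = A.shape[0]
    M = A.astype(float) + np.eye(n)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iter):
        new = np.linalg.matrix_power(M, params.expansion)
        np.power(new, params.inflation, out=new)
        new[new < params.prune_threshold] = 0.0
        colsums = new.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0  # fully pruned column: keep zeros
        new /= colsums
        diff = np.abs(new - M).max()
        M = new
        if diff < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", params.max_iter)

    attractors = np.flatnonzero(M.sum(axis=1) > 0)
    # union attractors whose row supports overlap (one attractor system each)
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractor_set = {int(i) for i in attractors}
    supports = {int(i): set(np.flatnonzero(M[i] > 0)) for i in attractors}
    # attractors attracted to one another belong to the same attractor system
    for i, sup in supports.items():
        for j in sup & attractor_set:
            ra, rb = find(i), find(j)
            if ra != rb:
                parent[ra] = rb
    systems: dict[int, set[int]] = {}
    for i, sup in supports.items():
        systems.setdefault(find(i), set()).update(sup)

    clusters = list(systems.values())
    # any node with no attractor mass (pruned away) becomes a singleton
    covered = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in covered:
            clusters.append({j})
    return clusters, converged


def mcl_cluster(
    net: InteractionNetwork, params: MCLParams = MCLParams(), source: str = "custom"
) -> list[GeneModule]:
    """Partition a network into modules with MCL.

    Nodes claimed by several attractor systems go to the largest cluster,
    ties broken lexicographically by the cluster's smallest gene symbol, so
    the output is a deterministic partition covering every node.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot cluster an empty network")
    genes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for e in net.graph.edges:
        i, j = index[e[0]], index[e[1]]
        A[i, j] = A[j, i] = 1.0

    raw_clusters, _ = _mcl_partition(A, params)
    named = [sorted(genes[i] for i in c) for c in raw_clusters]
    # resolve overlaps: largest cluster wins, tie-break by smallest symbol
    order = sorted(range(len(named)), key=lambda c: (-len(named[c]), named[c][0]))
    assigned: set[str] = set()
    final: list[list[str]] = []
    for c in order:
        members = [g for g in named[c] if g not in assigned]
        if members:
            assigned.update(members)
            final.append(members)
    final.sort(key=lambda ms: (-len(ms), ms[0]))
    return [
        GeneModule(id=f"{source}{k + 1}", genes=frozenset(ms), source=source)
        for k, ms in enumerate(final)
    ]


def mine_disease_modules(
    net: InteractionNetwork,
    seeds: GeneSet,
    k: int = 3,
    params: MCLParams = MCLParams(),
) -> list[GeneModule]:
    """Mine modules from the seed set's k-step neighborhood subnetwork.

    Every cluster is kept as a module whether or not it contains a seed
    (no minimum-seed requirement); modules are tagged by the seed set's
    disease side.
    """
    sub = k_step_neighborhood(net, seeds, k)
    source = _SOURCE_FOR_ROLE.get(seeds.role, "custom")
    return mcl_cluster(sub, params, source=source)


def read_modules_tsv(path) -> list[GeneModule]:
    modules = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("module_id\t"):
                continue
            mid, source, _, genes = line.rstrip("\n").split("\t")
            modules.append(
                GeneModule(id=mid, genes=frozenset(genes.split(",")), source=source)
            )
    return modules


def write_modules_tsv(modules: list[GeneModule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tsource\tn_genes\tgenes\n")
        for m in modules:
            fh.write(f"{m.id}\t{m.source}\t{len(m)}\t{','.join(sorted(m.genes))}\n")
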