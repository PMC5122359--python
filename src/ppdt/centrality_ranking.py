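"""Multi-centrality gene prioritization: the G-rank.

Within a module's induced subgraph, each gene receives four centrality
values — degree, closeness (inverse mean geodesic distance), betweenness
(fraction of shortest paths through the gene) and PageRank — and a rank
per metric (1 = most central).  The G-rank aggregates the four rank
columns by the geometric mean,

    G(g) = rank_ascending( (R_degree * R_betweenness * R_closeness * R_pagerank)^(1/4) ),

so a gene must be consistently central under all four views to rank high.
Only ranks enter the aggregate; any strictly monotone transformation of the
raw centrality values leaves the G-rank unchanged.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from ppdt.network_io import InteractionNetwork

METRICS = ("degree", "betweenness", "closeness", "pagerank")


def compute_centralities(
    module_net: InteractionNetwork,
    damping: float = 0.85,
    allow_disconnected: bool = False,
) -> pd.DataFrame:
    """Degree, closeness, betweenness and PageRank for every module gene.

    Closeness is the inverse of the mean shortest-path distance to the other
    n-1 genes; betweenness uses the standard undirected normalization (the
    constant factor relative to ordered-pair counting cancels in ranking);
    PageRank uses uniform teleportation with the given damping, iterated to
    tolerance 1e-10.

    The module is expected to be connected (MCL modules are, by
    construction).  With ``allow_disconnected`` closeness averages over
    reachable genes only, betweenness is computed per component and PageRank
    on the whole graph; otherwise a disconnected input is an error.
    """
    g = module_net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty module network")
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    if not nx.is_connected(g):
        if not allow_disconnected:
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(
                f"module network is disconnected ({len(comps)} components: "
                f"{[c[:3] for c in comps]}...); pass allow_disconnected=True "
                "for the per-component fallback"
            )
        closeness = nx.closeness_centrality(g, wf_improved=False)
        betweenness: dict[str, float] = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            betweenness.update(nx.betweenness_centrality(sub, normalized=True))
    else:
        closeness = nx.closeness_centrality(g, wf_improved=False)
        betweenness = nx.betweenness_centrality(g, normalized=True)
    degree = dict(g.degree())
    if n == 1:
        pagerank = {next(iter(g.nodes)): 1.0}
    else:
        pagerank = nx.pagerank(g, alpha=damping, tol=1e-10, max_iter=1000)
    genes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [float(degree[x]) for x in genes],
            "betweenness": [betweenness[x] for x in genes],
            "closeness": [closeness[x] for x in genes],
            "pagerank": [pagerank[x] for x in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def rank_metric(
    values: pd.Series, higher_is_better: bool = True, tie_policy: str = "ordinal"
) -> pd.Series:
    """Per-gene ranks, 1 = most central.

    The default ordinal policy breaks ties lexicographically by gene symbol,
    so the output is always a permutation of 1..n and identical inputs give
    identical ranks.  ``tie_policy="average"`` yields fractional mid-ranks
    instead.
    """
    if tie_policy not in ("ordinal", "average"):
        raise ValueError("tie_policy must be 'ordinal' or 'average'")
    v = values.sort_index()
    key = -v if higher_is_better else v
    if tie_policy == "average":
        ranks = key.rank(method="average")
    else:
        order = sorted(v.index, key=lambda g: (key[g], g))
        ranks = pd.Series({g: i for i, g in enumerate(order, start=1)}, name=values.name)
    return ranks.reindex(values.index).astype(float)


def add_ranks(table: pd.DataFrame, tie_policy: str = "ordinal") -> pd.DataFrame:
    """Append rank_<metric> columns for the four centrality columns."""
    out = table.copy()
    for m in METRICS:
        out[f"rank_{m}"] = rank_metric(table[m], higher_is_better=True, tie_policy=tie_policy)
    return out


def aggregate_ranks(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean rank and final G-rank from four per-metric rank columns.

    ``rank_table`` must hold the columns rank_degree, rank_betweenness,
    rank_closeness and rank_pagerank (any extra columns are carried
    through).  The geometric mean is the fourth root of the product of the
    four ranks; the G-rank orders the geometric means ascending (1 =
    smallest), ties broken lexicographically by gene symbol.
    """
    out = rank_table.copy()
    cols = [f"rank_{m}" for m in METRICS]
    missing = [c for c in cols if c not in out.columns]
    if missing:
        raise ValueError(f"missing rank columns: {missing}")
    out["geometric_mean"] = np.power(out[cols].prod(axis=1), 0.25)
    order = sorted(out.index, key=lambda g: (out.loc[g, "geometric_mean"], g))
    out["g_rank"] = pd.Series({g: i for i, g in enumerate(order, start=1)}).reindex(out.index)
    return out


def g_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Alias of :func:`aggregate_ranks` on a table with rank columns filled."""
    return aggregate_ranks(table)


def centrality_table(
    module_net: InteractionNetwork,
    damping: float = 0.85,
    tie_policy: str = "ordinal",
    allow_disconnected: bool = False,
) -> pd.DataFrame:
    """Full prioritization table: values, per-metric ranks, G-rank."""
    values = compute_centralities(module_net, damping=damping, allow_disconnected=allow_disconnected)
    return aggregate_ranks(add_ranks(values, tie_policy=tie_policy))


def write_rank_tsv(table: pd.DataFrame, path) -> None:
    cols = (
        ["g_rank"]
        + [f"rank_{m}" for m in METRICS]
        + ["geometric_mean"]
        + list(METRICS)
    )
    table.sort_values("g_rank")[cols].to_csv(path, sep="\t")
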