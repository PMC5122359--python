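"""Hypergeometric functional enrichment and final target selection.

The candidate module's genes, pooled with the disease-A genes, are tested
against every annotation term: with a universe of N genes of which M carry
the term, and a query of n genes of which k carry it, the enrichment
p-value is the hypergeometric upper tail P(X >= k).  Benjamini-Hochberg
FDR correction is applied across all tested terms; a term is significant
when q < alpha (default 0.05).

A candidate module is functionally consistent with the disease when enough
significant terms are hit by module genes and disease-A genes together.
Final potential targets are the module genes in the upper quartile of the
G-rank that also appear among the hits of at least one significant term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ppdt.network_io import AnnotationCatalog, GeneSet
from ppdt.similarity_pairing import CandidateModule


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment outcome for one query set."""

    term_id: str
    category: str
    N: int  # universe size
    n: int  # query size (within universe)
    M: int  # term size (within universe)
    k: int  # query-term overlap
    p_value: float
    q_value: float
    significant: bool
    hit_genes: frozenset[str]


@dataclass(frozen=True)
class TargetSelection:
    """Genes passing both the G-rank quartile and the enrichment criterion."""

    module_id: str
    cutoff_rank: int
    selected: tuple[str, ...]
    supporting_terms: dict[str, tuple[str, ...]]  # gene -> significant term ids


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term genes in a size-n draw without replacement from a
    universe of N genes containing M term genes.  Evaluated through the
    log-space survival function for numerical stability; k = 0 returns
    exactly 1.
    """
    for name, v in (("k", k), ("M", M), ("n", n), ("N", N)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if M > N or n > N:
        raise ValueError(f"M={M} and n={n} must not exceed N={N}")
    if k > min(n, M):
        raise ValueError(f"k={k} exceeds min(n={n}, M={M})")
    if k == 0:
        return 1.0
    logsf = stats.hypergeom.logsf(k - 1, N, M, n)
    return float(min(1.0, math.exp(logsf)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    module: CandidateModule | frozenset[str] | set[str],
    disease_A: GeneSet,
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment of the pooled module + disease-A query over a catalog.

    The query is (module genes ∪ disease-A genes) ∩ universe; every catalog
    term is tested and BH-adjusted jointly across categories.  Results come
    back sorted by ascending p-value.
    """
    if len(catalog) == 0:
        raise ValueError("annotation catalog is empty")
    module_genes = module.genes if isinstance(module, CandidateModule) else frozenset(module)
    query = (module_genes | disease_A.genes) & catalog.universe
    if not query:
        raise ValueError("query does not intersect the annotation universe")
    N = len(catalog.universe)
    n = len(query)
    rows = []
    for term in catalog.terms:
        term_genes = term.genes & catalog.universe
        hits = query & term_genes
        p = hypergeom_upper_tail(len(hits), len(term_genes), n, N)
        rows.append((term, len(term_genes), hits, p))
    q_values = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            category=term.category,
            N=N,
            n=n,
            M=M,
            k=len(hits),
            p_value=p,
            q_value=q,
            significant=q < alpha,
            hit_genes=frozenset(hits),
        )
        for (term, M, hits, p), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def functional_consistency(
    module: CandidateModule,
    results: list[EnrichmentResult],
    disease_A: GeneSet,
    min_terms: int = 1,
) -> bool:
    """Does the module share significant function with the disease-A genes?

    True iff at least ``min_terms`` significant terms have hit genes from
    the module *and* from the disease-A set (one gene may provide both).
    Candidates failing this are dropped from further analysis.
    """
    shared = 0
    for r in results:
        if not r.significant:
            continue
        if (r.hit_genes & module.genes) and (r.hit_genes & disease_A.genes):
            shared += 1
            if shared >= min_terms:
                return True
    return False


def select_targets(
    table: pd.DataFrame,
    results: list[EnrichmentResult],
    module_id: str = "",
) -> TargetSelection:
    """Upper-quartile, enrichment-supported genes of a prioritized module.

    ``table`` is the module's centrality table with a ``g_rank`` column
    over its n genes.  The quartile cutoff admits ceil(n/4) genes by
    G-rank; a gene is selected when it also appears among the hit genes of
    at least one significant term.  Each selected gene carries its
    supporting term ids.
    """
    n = len(table)
    cutoff = math.ceil(n / 4)
    top = set(table.index[table["g_rank"] <= cutoff])
    support: dict[str, list[str]] = {}
    for r in results:
        if not r.significant:
            continue
        for gene in r.hit_genes & top:
            support.setdefault(gene, []).append(r.term_id)
    selected = sorted(support, key=lambda g: table.loc[g, "g_rank"])
    return TargetSelection(
        module_id=module_id,
        cutoff_rank=cutoff,
        selected=tuple(selected),
        supporting_terms={g: tuple(sorted(ts)) for g, ts in support.items()},
    )


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tcategory\tk\tM\tn\tN\tp_value\tq_value\tsignificant\thit_genes\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.category}\t{r.k}\t{r.M}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{int(r.significant)}\t"
                f"{','.join(sorted(r.hit_genes))}\n"
            )


def write_targets_tsv(sel: TargetSelection, table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tg_rank\tsupporting_terms\n")
        for g in sel.selected:
            fh.write(
                f"{g}\t{int(table.loc[g, 'g_rank'])}\t{','.join(sel.supporting_terms[g])}\n"
            )
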