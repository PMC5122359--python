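"""Readers and writers for the pipeline's external formats.

All tabular files are plain TSV: tab-separated, UTF-8, ``#`` comment lines,
no quoting.  Gene symbols are whitespace-trimmed and uppercased on ingest;
no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = frozenset({"disease_A", "disease_B", "drug_target_B", "custom"})
STATUSES = ("normal", "disease", "treated")
CATEGORIES = frozenset({"BP", "MF", "pathway"})


class ParseError(ValueError):
    """A malformed input file (carries the offending line number)."""


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected, simple protein-protein interaction network.

    Self-loops and duplicate (including reversed) edges are forbidden by
    construction: build instances through :meth:`from_edges`, which
    simplifies its input and reports what it dropped.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        n_loops = 0
        n_dups = 0
        for a, b in edges:
            a, b = _norm(a), _norm(b)
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dups += 1
                continue
            g.add_edge(a, b)
        for n in nodes:
            g.add_node(_norm(n))
        if n_loops or n_dups:
            logger.info(
                "network simplified: dropped %d self-loops, %d duplicate edges",
                n_loops,
                n_dups,
            )
        return cls(g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def induced(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``nodes`` (unknown symbols ignored)."""
        keep = set(nodes) & set(self.graph.nodes)
        return InteractionNetwork(nx.Graph(self.graph.subgraph(keep)))


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a pipeline role."""

    name: str
    role: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(_norm(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    category: str  # BP | MF | pathway
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no genes")


@dataclass(frozen=True)
class AnnotationCatalog:
    """A term -> genes catalog (GO BP/MF plus pathways) with a gene universe.

    The universe defaults to the union of all term genes; a wider universe
    (e.g. every gene on a platform) may be supplied explicitly.
    """

    terms: tuple[AnnotationTerm, ...]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate term ids: {dup}")
        union = frozenset().union(*(t.genes for t in self.terms)) if self.terms else frozenset()
        if not self.universe:
            object.__setattr__(self, "universe", union)
        elif not union <= self.universe:
            raise ValueError("universe does not cover all annotated genes")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A probes/genes x samples expression matrix with sample statuses.

    ``values`` rows are probe or gene identifiers; ``probe_to_gene`` maps
    probes onto gene symbols (absent mapping means rows already are genes).
    ``status`` assigns each sample one of normal/disease/treated;
    ``pair_id`` optionally links each disease sample to the treated sample
    from the same subject.
    """

    values: pd.DataFrame  # rows x samples, float
    status: pd.Series  # sample -> status
    probe_to_gene: Mapping[str, str] | None = None
    pair_id: pd.Series | None = None  # sample -> subject label

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.status.index):
            raise ValueError("sample order of matrix and status differ")
        bad = set(self.status) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")
        if self.pair_id is not None:
            paired = self.pair_id.dropna()
            for pid, members in paired.groupby(paired).groups.items():
                st = sorted(self.status[list(members)])
                if st != ["disease", "treated"]:
                    raise ValueError(
                        f"pair {pid!r} must link exactly one disease and one treated sample"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def status_counts(self) -> dict[str, int]:
        return self.status.value_counts().to_dict()

    def gene_values(self, gene: str) -> pd.DataFrame:
        """All rows mapping to ``gene`` (possibly several probes)."""
        gene = _norm(gene)
        if self.probe_to_gene is None:
            rows = [r for r in self.values.index if _norm(str(r)) == gene]
        else:
            rows = [r for r in self.values.index if self.probe_to_gene.get(r) == gene]
        return self.values.loc[rows]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given samples; pair links broken by the subset are dropped."""
        keep = [s for s in self.values.columns if s in set(samples)]
        pair_id = None
        if self.pair_id is not None:
            pair_id = self.pair_id[keep].copy()
            counts = pair_id.value_counts()
            broken = counts[counts < 2].index
            pair_id[pair_id.isin(broken)] = None
        return ExpressionMatrix(
            values=self.values[keep],
            status=self.status[keep],
            probe_to_gene=self.probe_to_gene,
            pair_id=pair_id,
        )


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column edge list into a simplified network.

    Self-loops are dropped (the node is kept, isolated) and duplicate or
    reversed-duplicate edges collapse to one; both are counted in a log
    message.  A line with fewer than two fields is a parse error.
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
        edges.append((fields[0], fields[1]))
    if not edges:
        logger.warning("edge list %s is empty", path)
    return InteractionNetwork.from_edges(edges)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_set(path: str | Path, role: str, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set; dedups and uppercases."""
    genes = {_norm(line.split()[0]) for _, line in _data_lines(path)}
    if not genes:
        raise ParseError(f"{path}: gene set is empty")
    return GeneSet(name=name or Path(path).stem, role=role, genes=frozenset(genes))


DEFAULT_CATEGORY_PREFIXES: dict[str, str] = {
    "GO_BP:": "BP",
    "GO_MF:": "MF",
    "KEGG:": "pathway",
}


def read_gmt(
    path: str | Path,
    category_prefixes: Mapping[str, str] = DEFAULT_CATEGORY_PREFIXES,
) -> AnnotationCatalog:
    """Read a standard GMT file (term, description, genes...).

    The term category is inferred from a configurable id-prefix convention
    (default ``GO_BP:``/``GO_MF:``/``KEGG:``), falling back to ``pathway``.
    Terms with zero genes are skipped with a warning; a duplicate term id is
    an error.
    """
    terms: list[AnnotationTerm] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: GMT line needs at least id and description")
        term_id = fields[0].strip()
        genes = frozenset(_norm(g) for g in fields[2:] if g.strip())
        if not genes:
            logger.warning("%s:%d: term %s has no genes, skipped", path, lineno, term_id)
            continue
        if term_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        seen.add(term_id)
        category = "pathway"
        for prefix, cat in category_prefixes.items():
            if term_id.startswith(prefix):
                category = cat
                break
        terms.append(AnnotationTerm(term_id=term_id, category=category, genes=genes))
    return AnnotationCatalog(terms=tuple(terms))


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in catalog.terms:
            fh.write("\t".join([t.term_id, t.category, *sorted(t.genes)]) + "\n")


def read_expression(
    matrix_path: str | Path,
    pheno_path: str | Path,
    probe_map_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV plus a phenotype TSV (and optional probe map).

    The matrix has a header row of sample ids and row ids in the first
    column.  The phenotype table maps sample id -> status (normal, disease
    or treated) with an optional ``pair_id`` column linking each disease
    sample to its treated counterpart.  Samples present in the matrix but
    missing from the phenotype table are an error.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    pheno = pd.read_csv(pheno_path, sep="\t", comment="#", dtype=str)
    pheno = pheno.set_index(pheno.columns[0])
    missing = [s for s in values.columns if s not in pheno.index]
    if missing:
        raise ParseError(f"{pheno_path}: samples missing from phenotype table: {missing}")
    pheno = pheno.loc[list(values.columns)]
    status = pheno.iloc[:, 0]
    status.name = "status"
    bad = sorted(set(status) - set(STATUSES))
    if bad:
        raise ParseError(f"{pheno_path}: unknown status labels {bad}")

    pair_id = None
    if "pair_id" in pheno.columns:
        pair_id = pheno["pair_id"]
        pair_id = pair_id.where(pair_id.notna() & (pair_id != ""))

    probe_to_gene = None
    if probe_map_path is not None:
        pm = pd.read_csv(
            probe_map_path, sep="\t", comment="#", header=None, dtype=str
        )
        probe_to_gene = {p: _norm(g) for p, g in zip(pm[0], pm[1])}

    return ExpressionMatrix(
        values=values.astype(float),
        status=status,
        probe_to_gene=probe_to_gene,
        pair_id=pair_id,
    )
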