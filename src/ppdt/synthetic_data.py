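"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the statistical structure the pipeline assumes in
real data — an interaction network with planted dense modules, two disease
gene sets concentrated in partially overlapping planted modules, drug
targets inside the shared module, an annotation catalog mirroring the
planted modules, and a three-status expression matrix (normal / disease /
treated, with paired disease-treated samples) in which the disease effect
is confined to the target genes.

Beyond the planted modules, a configurable number of loosely attached
background nodes emulates the periphery of a real interaction network;
their erratic cluster assignments are what give the cross-disease Jaccard
distribution its realistic long tail of small overlaps.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ppdt.network_io import (
    AnnotationCatalog,
    AnnotationTerm,
    ExpressionMatrix,
    GeneSet,
    InteractionNetwork,
    write_edge_list,
    write_gmt,
)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a synthetic study."""

    master_seed: int
    modules: tuple[frozenset[str], ...] = ()
    background: frozenset[str] = frozenset()
    network: InteractionNetwork | None = None
    shared_module_indices: tuple[int, ...] = ()
    a_module_indices: tuple[int, ...] = ()
    b_module_indices: tuple[int, ...] = ()
    genes_A: frozenset[str] = frozenset()
    genes_B: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    term_for_module: dict[int, str] = field(default_factory=dict)
    effect: float = 0.0
    nonresponders: frozenset[str] = frozenset()

    @property
    def shared_module(self) -> frozenset[str]:
        if not self.shared_module_indices:
            return frozenset()
        return frozenset().union(*(self.modules[i] for i in self.shared_module_indices))

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset().union(*self.modules, self.background)

    def to_json(self) -> str:
        payload = {
            "master_seed": self.master_seed,
            "modules": [sorted(m) for m in self.modules],
            "background": sorted(self.background),
            "shared_module_indices": list(self.shared_module_indices),
            "a_module_indices": list(self.a_module_indices),
            "b_module_indices": list(self.b_module_indices),
            "genes_A": sorted(self.genes_A),
            "genes_B": sorted(self.genes_B),
            "targets": sorted(self.targets),
            "term_for_module": {str(k): v for k, v in self.term_for_module.items()},
            "effect": self.effect,
            "nonresponders": sorted(self.nonresponders),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def generate_network(
    n_modules: int = 8,
    module_size: int = 20,
    p_in: float = 0.9,
    p_out: float = 0.01,
    n_background: int = 70,
    seed: int = 0,
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Planted-partition network plus loosely attached background nodes.

    Within-module node pairs are joined with probability p_in, cross-module
    pairs with p_out; a module node left isolated is reconnected to a
    random module-mate.  Each background node attaches with 1-3 edges to
    uniformly chosen earlier nodes, forming stray periphery (chains,
    pendants) outside every planted module.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if n_modules < 1 or module_size < 2:
        raise ValueError("need at least one module of size >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_modules * module_size))
    modules = [
        frozenset(
            f"G{m * module_size + i + 1:0{width}d}" for i in range(module_size)
        )
        for m in range(n_modules)
    ]
    edges: list[tuple[str, str]] = []
    for mod in modules:
        members = sorted(mod)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_in:
                    edges.append((members[i], members[j]))
    all_module_genes = sorted(set().union(*modules))
    module_of = {g: k for k, mod in enumerate(modules) for g in mod}
    if p_out > 0:
        for i in range(len(all_module_genes)):
            for j in range(i + 1, len(all_module_genes)):
                a, b = all_module_genes[i], all_module_genes[j]
                if module_of[a] != module_of[b] and rng.random() < p_out:
                    edges.append((a, b))
    # reconnect isolated module nodes to a random module-mate
    touched = {g for e in edges for g in e}
    for mod in modules:
        for g in sorted(mod):
            if g not in touched:
                mate = rng.choice([x for x in sorted(mod) if x != g])
                edges.append((g, str(mate)))
                touched.add(g)
    # background periphery: a sparse branching web of chains hanging off the
    # dense core.  Deep peripheral nodes lie beyond the seeds' k-step
    # horizon, so the two disease neighborhoods differ at their frontiers
    # (as they do in a real interaction network) instead of coinciding.
    background = [f"B{i + 1:03d}" for i in range(n_background)]
    i = 0
    while i < n_background:
        length = int(rng.integers(2, 7))
        if i == 0 or rng.random() < 0.5:
            anchor = str(rng.choice(all_module_genes))
        else:
            anchor = str(rng.choice(background[:i]))
        prev = anchor
        for _ in range(min(length, n_background - i)):
            node = background[i]
            edges.append((prev, node))
            if rng.random() < 0.05:  # occasional shortcut elsewhere
                pool = all_module_genes + background[:i]
                edges.append((node, str(rng.choice(pool))))
            prev = node
            i += 1
    net = InteractionNetwork.from_edges(edges, nodes=all_module_genes + background)
    truth = SyntheticTruth(
        master_seed=seed,
        modules=tuple(modules),
        background=frozenset(background),
        network=net,
    )
    return net, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_A: int = 12,
    n_B: int = 14,
    n_targets: int = 5,
    overlap_modules: int = 1,
    seed: int = 0,
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Disease-A genes, disease-B genes and disease-B drug targets.

    The first ``overlap_modules`` planted modules are shared between the
    diseases; the next two are A-specific, the following two B-specific.
    Each disease set draws at least two genes from the shared module(s) and
    the rest from its own side.  Targets are the most central members of
    the shared module(s) (top G-rank of the module's induced subgraph,
    which in a dense module essentially means its best-connected genes) —
    the premise being that drug targets sit at the core of the shared
    disease module.  Targets may coincide with disease genes (multi-role
    genes).
    """
    if truth.network is None or not truth.modules:
        raise ValueError("truth must come from generate_network")
    if len(truth.modules) < overlap_modules + 4:
        raise ValueError("need at least overlap_modules + 4 planted modules")
    rng = np.random.default_rng(seed)
    shared_idx = tuple(range(overlap_modules))
    a_idx = shared_idx + tuple(range(overlap_modules, overlap_modules + 2))
    b_idx = shared_idx + tuple(range(overlap_modules + 2, overlap_modules + 4))
    shared = sorted(frozenset().union(*(truth.modules[i] for i in shared_idx)))
    a_only = sorted(frozenset().union(*(truth.modules[i] for i in a_idx[overlap_modules:])))
    b_only = sorted(frozenset().union(*(truth.modules[i] for i in b_idx[overlap_modules:])))

    def draw(pool_shared, pool_own, n):
        if n < 2 or n - 2 > len(pool_own) + len(pool_shared) - 2:
            raise ValueError(f"cannot draw {n} genes from the designated modules")
        picked = list(rng.choice(pool_shared, size=2, replace=False))
        rest = sorted(set(pool_shared + pool_own) - set(picked))
        picked += list(rng.choice(rest, size=n - 2, replace=False))
        return frozenset(str(g) for g in picked)

    genes_a = draw(shared, a_only, n_A)
    genes_b = draw(shared, b_only, n_B)
    if n_targets > len(shared):
        raise ValueError("more targets requested than shared-module genes")
    from ppdt.centrality_ranking import centrality_table

    table = centrality_table(truth.network.induced(shared), allow_disconnected=True)
    by_centrality = table.sort_values("g_rank").index
    targets = frozenset(by_centrality[:n_targets])
    truth.genes_A, truth.genes_B, truth.targets = genes_a, genes_b, targets
    truth.shared_module_indices = shared_idx
    truth.a_module_indices = a_idx
    truth.b_module_indices = b_idx
    return (
        GeneSet(name="disease_A_genes", role="disease_A", genes=genes_a),
        GeneSet(name="disease_B_genes", role="disease_B", genes=genes_b),
        GeneSet(name="drug_targets_B", role="drug_target_B", genes=targets),
    )


def generate_annotation(
    truth: SyntheticTruth,
    n_noise_terms: int = 20,
    jitter: float = 0.0,
    seed: int = 0,
) -> AnnotationCatalog:
    """One annotation term per planted module plus random noise terms.

    A module's term contains its gene set, with a ``jitter`` fraction of
    members swapped for random outside genes; noise terms draw 10-30 genes
    uniformly.  The universe is every network gene, so enrichment operates
    against the full gene background.
    """
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.all_genes)
    prefixes = ("GO_BP:", "GO_MF:", "KEGG:")
    terms: list[AnnotationTerm] = []
    for i, mod in enumerate(truth.modules):
        genes = sorted(mod)
        n_swap = int(round(jitter * len(genes)))
        if n_swap:
            out = rng.choice(genes, size=n_swap, replace=False)
            pool = sorted(set(universe) - set(genes))
            repl = rng.choice(pool, size=n_swap, replace=False)
            genes = sorted((set(genes) - set(map(str, out))) | set(map(str, repl)))
        term_id = f"GO_BP:PLANTED_MODULE_{i + 1}"
        truth.term_for_module[i] = term_id
        terms.append(AnnotationTerm(term_id=term_id, category="BP", genes=frozenset(genes)))
    for j in range(n_noise_terms):
        size = int(rng.integers(10, 31))
        genes = frozenset(str(g) for g in rng.choice(universe, size=size, replace=False))
        prefix = prefixes[j % len(prefixes)]
        cat = {"GO_BP:": "BP", "GO_MF:": "MF", "KEGG:": "pathway"}[prefix]
        terms.append(AnnotationTerm(term_id=f"{prefix}NOISE_{j + 1}", category=cat, genes=genes))
    return AnnotationCatalog(terms=tuple(terms), universe=frozenset(universe))


def generate_expression(
    truth: SyntheticTruth,
    n_normal: int = 13,
    n_pairs: int = 10,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    probes_per_gene: int = 2,
    reversion: float = 1.0,
    nonresponder_fraction: float = 0.5,
    nonresponder_shift: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Log-scale expression with an additive status effect on target genes.

    Per gene, baseline ~ Normal(7, 1).  Disease samples add ``effect`` on
    target genes; a treated sample reverts the target genes toward baseline
    by the ``reversion`` fraction.  Disease and treated samples are paired
    one-to-one.  A ``nonresponder_fraction`` of the treated samples does
    not revert and additionally drifts by a global additive shift of
    magnitude ``nonresponder_shift`` (random sign) — the deviant samples
    the consistency filter is meant to catch.  Probe rows per gene carry
    small fixed offsets; i.i.d. Normal(0, noise_sd) noise is added
    everywhere.
    """
    if effect < 0 or noise_sd < 0 or probes_per_gene < 1:
        raise ValueError("invalid expression parameters")
    if n_normal < 3 or n_pairs < 3:
        raise ValueError("need at least 3 samples per status")
    if not 0 <= nonresponder_fraction <= 1 or not 0 <= reversion <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.all_genes)
    is_target = np.array([g in truth.targets for g in genes], dtype=float)
    baseline = rng.normal(7.0, 1.0, size=len(genes))

    normals = [f"N{i + 1:02d}" for i in range(n_normal)]
    diseased = [f"D{i + 1:02d}" for i in range(n_pairs)]
    treated = [f"T{i + 1:02d}" for i in range(n_pairs)]
    n_nonresp = int(round(nonresponder_fraction * n_pairs))
    nonresp = set(
        str(t) for t in rng.choice(treated, size=n_nonresp, replace=False)
    )
    truth.effect = effect
    truth.nonresponders = frozenset(nonresp)

    gene_level: dict[str, np.ndarray] = {}
    for s in normals:
        gene_level[s] = baseline.copy()
    for s in diseased:
        gene_level[s] = baseline + effect * is_target
    for s in treated:
        if s in nonresp:
            shift = nonresponder_shift * (1 if rng.random() < 0.5 else -1)
            gene_level[s] = baseline + effect * is_target + shift
        else:
            gene_level[s] = baseline + effect * (1 - reversion) * is_target

    probe_offsets = rng.normal(0.0, 0.25, size=probes_per_gene)
    probe_ids = [f"{g}_p{j + 1}" for g in genes for j in range(probes_per_gene)]
    probe_to_gene = {f"{g}_p{j + 1}": g for g in genes for j in range(probes_per_gene)}
    samples = normals + diseased + treated
    values = np.empty((len(probe_ids), len(samples)))
    for c, s in enumerate(samples):
        per_probe = np.repeat(gene_level[s], probes_per_gene) + np.tile(
            probe_offsets, len(genes)
        )
        values[:, c] = per_probe + rng.normal(0.0, noise_sd, size=len(probe_ids))

    status = pd.Series(
        ["normal"] * n_normal + ["disease"] * n_pairs + ["treated"] * n_pairs,
        index=samples,
        name="status",
    )
    pair_id = pd.Series([None] * n_normal + [f"P{i + 1:02d}" for i in range(n_pairs)] * 2,
                        index=samples, name="pair_id", dtype=object)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        status=status,
        probe_to_gene=probe_to_gene,
        pair_id=pair_id,
    )


def write_fixture(out_dir: str | Path, seed: int = 0, **params) -> dict[str, Path]:
    """Generate a complete fixture directory in the formats the readers expect.

    Writes the edge list, the three gene-set files, the GMT catalog, the
    expression and phenotype tables, the probe map and a ground-truth JSON.
    ``params`` may override any generator default, prefixed by stage
    (``network_``, ``genes_``, ``annotation_``, ``expression_``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage_params(prefix):
        return {k[len(prefix):]: v for k, v in params.items() if k.startswith(prefix)}

    net, truth = generate_network(seed=seed, **stage_params("network_"))
    gs_a, gs_b, gs_t = generate_gene_sets(truth, seed=seed + 1, **stage_params("genes_"))
    catalog = generate_annotation(truth, seed=seed + 2, **stage_params("annotation_"))
    expr = generate_expression(truth, seed=seed + 3, **stage_params("expression_"))

    paths = {
        "network": out / "network.tsv",
        "genes_a": out / "disease_A_genes.txt",
        "genes_b": out / "disease_B_genes.txt",
        "targets_b": out / "drug_targets_B.txt",
        "gmt": out / "annotation.gmt",
        "expr": out / "expression.tsv",
        "pheno": out / "phenotype.tsv",
        "probe_map": out / "probe_map.tsv",
        "truth": out / "truth.json",
    }
    write_edge_list(net, paths["network"])
    for key, gs in (("genes_a", gs_a), ("genes_b", gs_b), ("targets_b", gs_t)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            fh.write("\n".join(sorted(gs.genes)) + "\n")
    write_gmt(catalog, paths["gmt"])
    expr.values.to_csv(paths["expr"], sep="\t", index_label="probe_id")
    pheno = pd.DataFrame({"sample": expr.samples,
                          "status": [expr.status[s] for s in expr.samples],
                          "pair_id": [expr.pair_id[s] if expr.pair_id is not None else ""
                                      for s in expr.samples]})
    pheno["pair_id"] = pheno["pair_id"].fillna("")
    pheno.to_csv(paths["pheno"], sep="\t", index=False)
    with open(paths["probe_map"], "w", encoding="utf-8") as fh:
        for probe, gene in sorted(expr.probe_to_gene.items()):
            fh.write(f"{probe}\t{gene}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
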