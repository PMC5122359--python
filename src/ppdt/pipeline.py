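"""End-to-end orchestration of the drug-target discovery pipeline.

Stages: mine disease-A and disease-B modules from seed neighborhoods →
pair modules by Jaccard similarity and apply the median threshold → filter
pair intersections to candidate shared modules → prioritize candidate
genes by G-rank → enrichment and functional-consistency filtering → final
target selection → SVM efficiency evaluation of the selected targets
against comparison feature sets, before and after the sample-consistency
filter.  Every intermediate table is written as TSV, stamped with a hash of
the configuration, and a deterministic summary JSON closes the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from ppdt import (
    centrality_ranking,
    efficiency_eval,
    enrichment,
    module_mining,
    network_io,
    similarity_pairing,
)
from ppdt.network_io import AnnotationCatalog

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and input paths for one pipeline run."""

    network: str
    genes_a: str
    genes_b: str
    targets_b: str
    gmt: str
    out_dir: str
    expr: str | None = None
    pheno: str | None = None
    probe_map: str | None = None

    k: int = 3
    inflation: float = 1.8
    prune_threshold: float = 1e-5
    mcl_tol: float = 1e-6
    mcl_max_iter: int = 100
    median_scope: str = "nonzero"
    damping: float = 0.85
    tie_policy: str = "ordinal"
    allow_disconnected: bool = True
    universe_scope: str = "catalog"  # catalog | network
    alpha: float = 0.05
    min_terms: int = 1
    folds: int = 5
    repeats: int = 1000
    seed: int = 17
    consistency: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("network", "genes_a", "genes_b", "targets_b", "gmt"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name}: {p}")
        if (self.expr is None) != (self.pheno is None):
            raise ValueError("expr and pheno must be given together")
        if self.median_scope not in ("nonzero", "all"):
            raise ValueError("median_scope must be 'nonzero' or 'all'")
        if self.universe_scope not in ("catalog", "network"):
            raise ValueError("universe_scope must be 'catalog' or 'network'")
        if self.inflation <= 1 or not 0 < self.damping < 1:
            raise ValueError("invalid inflation or damping")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(path: Path, config_hash: str) -> None:
    """Prepend a comment line naming the config hash to a text artifact."""
    text = path.read_text(encoding="utf-8")
    path.write_text(f"# config_hash={config_hash}\n" + text, encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary (also written as JSON)."""
    config.validate()
    h = config.config_hash
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        _stamp(path, h)

    net = network_io.read_edge_list(config.network)
    genes_a = network_io.read_gene_set(config.genes_a, role="disease_A")
    genes_b = network_io.read_gene_set(config.genes_b, role="disease_B")
    targets_b = network_io.read_gene_set(config.targets_b, role="drug_target_B")
    catalog = network_io.read_gmt(config.gmt)
    if config.universe_scope == "network":
        catalog = AnnotationCatalog(
            terms=catalog.terms, universe=catalog.universe | net.nodes
        )
    logger.info(
        "inputs: network %d nodes / %d edges; %d A genes, %d B genes, %d targets, %d terms",
        net.n_nodes, net.n_edges, len(genes_a), len(genes_b), len(targets_b), len(catalog),
    )

    params = module_mining.MCLParams(
        inflation=config.inflation,
        prune_threshold=config.prune_threshold,
        max_iter=config.mcl_max_iter,
        tol=config.mcl_tol,
    )
    p_modules = module_mining.mine_disease_modules(net, genes_a, config.k, params)
    t_modules = module_mining.mine_disease_modules(net, genes_b, config.k, params)
    emit("modules_A.tsv", module_mining.write_modules_tsv, p_modules)
    emit("modules_B.tsv", module_mining.write_modules_tsv, t_modules)
    logger.info("mined %d A-modules, %d B-modules", len(p_modules), len(t_modules))

    pairs, threshold = similarity_pairing.pair_and_threshold(
        p_modules, t_modules, median_scope=config.median_scope
    )
    emit("pairs.tsv", similarity_pairing.write_pairs_tsv, pairs)
    candidates = similarity_pairing.build_candidates(pairs, genes_a, genes_b, targets_b)
    emit("candidates.tsv", similarity_pairing.write_candidates_tsv, candidates)
    logger.info(
        "%d pairs above median J=%.4g; %d candidate modules", len(pairs), threshold, len(candidates)
    )

    summary: dict = {
        "config_hash": h,
        "config": config.to_dict(),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_modules_A": len(p_modules),
        "n_modules_B": len(t_modules),
        "n_pairs_retained": len(pairs),
        "jaccard_threshold": threshold,
        "n_candidates": len(candidates),
        "final_modules": [],
        "selected_targets": {},
        "evaluation": {},
    }

    final = []
    tables = {}
    for cand in candidates:
        table = centrality_ranking.centrality_table(
            net.induced(cand.genes),
            damping=config.damping,
            tie_policy=config.tie_policy,
            allow_disconnected=config.allow_disconnected,
        )
        tables[cand.id] = table
        emit(f"rank_{cand.id}.tsv", centrality_ranking.write_rank_tsv, table)
        results = enrichment.enrich(cand, genes_a, catalog, alpha=config.alpha)
        emit(f"enrichment_{cand.id}.tsv", enrichment.write_enrichment_tsv, results)
        if enrichment.functional_consistency(cand, results, genes_a, min_terms=config.min_terms):
            sel = enrichment.select_targets(table, results, module_id=cand.id)
            emit(f"targets_{cand.id}.tsv", enrichment.write_targets_tsv, sel, table)
            final.append(cand)
            summary["final_modules"].append(
                {"id": cand.id, "n_genes": len(cand), "genes": sorted(cand.genes)}
            )
            summary["selected_targets"][cand.id] = list(sel.selected)
            logger.info(
                "module %s passed functional consistency; %d targets selected",
                cand.id, len(sel.selected),
            )
        else:
            logger.info("module %s dropped: no shared significant function", cand.id)

    if not candidates:
        logger.warning("no candidate modules; pipeline terminates after pairing")

    if config.expr is not None and final:
        expr = network_io.read_expression(config.expr, config.pheno, config.probe_map)
        primary = final[0]
        feature_sets = {
            "selected_targets": set(summary["selected_targets"][primary.id]),
            "module": set(primary.genes),
            "disease_A_genes": set(genes_a.genes),
            "disease_B_genes": set(genes_b.genes),
            "drug_targets_B": set(targets_b.genes),
        }
        datasets = {"original": expr}
        if config.consistency:
            cr = efficiency_eval.consistency_check(expr, alpha=config.alpha)
            emit("consistency.tsv", efficiency_eval.write_consistency_tsv, cr)
            datasets["consistent"] = efficiency_eval.select_consistent_pairs(cr, expr)
        for ds_name, ds in datasets.items():
            for task in efficiency_eval.TASKS:
                for fs_name, fs_genes in feature_sets.items():
                    if not fs_genes:
                        continue
                    fm = efficiency_eval.build_features(ds, fs_genes, task)
                    report = efficiency_eval.cv_classify(
                        fm, folds=config.folds, repeats=config.repeats, seed=config.seed
                    )
                    key = f"{ds_name}.{task}.{fs_name}"
                    emit(
                        f"eval_{ds_name}_{task}_{fs_name}.tsv",
                        efficiency_eval.write_report_tsv,
                        report,
                    )
                    summary["evaluation"][key] = {
                        m: round(report.means[m], 6) for m in efficiency_eval.METRIC_NAMES
                    }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
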