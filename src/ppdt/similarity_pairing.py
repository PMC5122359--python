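"""Cross-disease module pairing by Jaccard similarity.

Every disease-A module is scored against every disease-B module with the
Jaccard index J = |P∩T| / |P∪T|.  Pairs whose J strictly exceeds the median
of the observed J values are "pathobiologically similar"; the shared gene
set of such a pair becomes a candidate module when it simultaneously
contains disease-A genes, disease-B genes and known disease-B drug targets.

The median is taken over the nonzero J values by default: with hundreds of
modules almost all cross pairs are disjoint, so a median over all pairs
degenerates to 0 and the threshold becomes vacuous.  ``median_scope="all"``
restores the literal all-pairs median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

from ppdt.module_mining import GeneModule
from ppdt.network_io import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModulePair:
    p_id: str
    t_id: str
    jaccard: float
    intersection: frozenset[str]


@dataclass(frozen=True)
class CandidateModule:
    """A shared module containing genes of every required role."""

    id: str
    genes: frozenset[str]
    contains_A: frozenset[str]
    contains_B: frozenset[str]
    contains_targets: frozenset[str]
    p_id: str = ""
    t_id: str = ""

    def __post_init__(self) -> None:
        if not (self.contains_A and self.contains_B and self.contains_targets):
            raise ValueError(
                f"candidate {self.id!r} must contain disease-A genes, "
                "disease-B genes and drug targets"
            )

    def __len__(self) -> int:
        return len(self.genes)


def jaccard(P: frozenset[str] | set[str], T: frozenset[str] | set[str]) -> float:
    """Jaccard similarity |P∩T| / |P∪T| of two nonempty gene sets."""
    if not P or not T:
        raise ValueError("jaccard requires nonempty sets")
    inter = len(P & T)
    if inter == 0:
        return 0.0
    return inter / len(P | T)


def pair_and_threshold(
    p_modules: list[GeneModule],
    t_modules: list[GeneModule],
    median_scope: str = "nonzero",
) -> tuple[list[ModulePair], float]:
    """Score all cross pairs and keep those with J strictly above the median.

    Returns the retained pairs (sorted by descending J) and the threshold
    used.  If every pair is disjoint the result is empty with a warning.
    """
    if not p_modules or not t_modules:
        raise ValueError("both module lists must be nonempty")
    if median_scope not in ("nonzero", "all"):
        raise ValueError("median_scope must be 'nonzero' or 'all'")
    scored: list[ModulePair] = []
    values: list[float] = []
    for p in p_modules:
        for t in t_modules:
            j = jaccard(p.genes, t.genes)
            values.append(j)
            if j > 0:
                scored.append(
                    ModulePair(
                        p_id=p.id, t_id=t.id, jaccard=j,
                        intersection=frozenset(p.genes & t.genes),
                    )
                )
    if not scored:
        logger.warning("all %d module pairs are disjoint", len(values))
        return [], 0.0
    pool = [v for v in values if v > 0] if median_scope == "nonzero" else values
    threshold = float(median(pool))
    kept = [mp for mp in scored if mp.jaccard > threshold]
    kept.sort(key=lambda mp: (-mp.jaccard, mp.p_id, mp.t_id))
    logger.info(
        "retained %d of %d overlapping pairs above median J %.4g",
        len(kept), len(scored), threshold,
    )
    return kept, threshold


def build_candidates(
    pairs: list[ModulePair],
    genes_A: GeneSet,
    genes_B: GeneSet,
    targets_B: GeneSet,
) -> list[CandidateModule]:
    """Filter thresholded pairs down to candidate shared drug-target modules.

    The pair's intersection gene set must contain at least one disease-A
    gene, one disease-B gene and one drug target; one gene may fill several
    roles at once.  Pairs with identical intersections collapse to a single
    candidate.
    """
    candidates: list[CandidateModule] = []
    seen: set[frozenset[str]] = set()
    for mp in pairs:
        if mp.intersection in seen:
            continue
        a = mp.intersection & genes_A.genes
        b = mp.intersection & genes_B.genes
        t = mp.intersection & targets_B.genes
        if a and b and t:
            seen.add(mp.intersection)
            candidates.append(
                CandidateModule(
                    id=f"candidate{len(candidates) + 1}",
                    genes=mp.intersection,
                    contains_A=frozenset(a),
                    contains_B=frozenset(b),
                    contains_targets=frozenset(t),
                    p_id=mp.p_id,
                    t_id=mp.t_id,
                )
            )
    return candidates


def write_pairs_tsv(pairs: list[ModulePair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("p_id\tt_id\tjaccard\tn_intersection\tgenes\n")
        for mp in pairs:
            fh.write(
                f"{mp.p_id}\t{mp.t_id}\t{mp.jaccard:.6g}\t"
                f"{len(mp.intersection)}\t{','.join(sorted(mp.intersection))}\n"
            )


def write_candidates_tsv(candidates: list[CandidateModule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "candidate_id\tp_id\tt_id\tn_genes\tdisease_A_genes\t"
            "disease_B_genes\tdrug_targets\tgenes\n"
        )
        for c in candidates:
            fh.write(
                f"{c.id}\t{c.p_id}\t{c.t_id}\t{len(c)}\t"
                f"{','.join(sorted(c.contains_A))}\t{','.join(sorted(c.contains_B))}\t"
                f"{','.join(sorted(c.contains_targets))}\t{','.join(sorted(c.genes))}\n"
            )
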