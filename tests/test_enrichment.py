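"""Hypergeometric enrichment against exhaustive enumeration, BH against a
hand-written step-up oracle, and the quartile target-selection rule."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ppdt import (
    GeneSet,
    bh_fdr,
    enrich,
    functional_consistency,
    hypergeom_upper_tail,
    select_targets,
)
from ppdt.network_io import AnnotationCatalog, AnnotationTerm
from ppdt.similarity_pairing import CandidateModule


def _upper_tail_by_enumeration(k, M, n, N):
    """P(X >= k) by enumerating every size-n draw from an N-element universe."""
    marked = set(range(M))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def _bh_step_up_oracle(p_values):
    """Textbook BH step-up: q_(i) = min_{j>=i} min(1, m * p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_pos in range(m, 0, -1):
        i = order[rank_pos - 1]
        running = min(running, m * p_values[i] / rank_pos)
        q[i] = min(1.0, running)
    return q


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_all_marked_drawn(self):
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_small_case(self):
        assert hypergeom_upper_tail(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_constraint_violations(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 5, 10)  # k > M
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 11, 5, 10)  # M > N
        with pytest.raises(ValueError):
            hypergeom_upper_tail(-1, 2, 2, 4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        M = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(M, n) + 1))
        assert hypergeom_upper_tail(k, M, n, N) == pytest.approx(
            _upper_tail_by_enumeration(k, M, n, N)
        )


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identical_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1], [float("nan")]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40))).tolist()
        assert bh_fdr(p) == pytest.approx(_bh_step_up_oracle(p))

    def test_q_monotone_in_p_rank_order(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1.0, size=30)
        q = np.asarray(bh_fdr(p.tolist()))
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _catalog(term_sets, universe=None):
    terms = tuple(
        AnnotationTerm(f"T{i}", "BP", frozenset(genes))
        for i, genes in enumerate(term_sets)
    )
    return AnnotationCatalog(terms=terms, universe=frozenset(universe or ()))


def _candidate(genes):
    g = frozenset(genes)
    return CandidateModule(
        id="c1", genes=g, contains_A=g, contains_B=g, contains_targets=g
    )


class TestEnrich:
    def test_exactly_matching_term_has_smallest_p(self):
        universe = {f"U{i}" for i in range(30)}
        target_term = {f"U{i}" for i in range(6)}
        cat = _catalog(
            [target_term, {f"U{i}" for i in range(10, 16)}, {f"U{i}" for i in range(20, 26)}],
            universe,
        )
        disease = GeneSet("A", "disease_A", frozenset({"U0", "U1"}))
        results = enrich(target_term, disease, cat)
        assert results[0].term_id == "T0"
        assert results[0].p_value == min(r.p_value for r in results)

    def test_disjoint_term_has_p_one(self):
        universe = {f"U{i}" for i in range(20)}
        cat = _catalog([{f"U{i}" for i in range(5)}, {f"U{i}" for i in range(10, 15)}], universe)
        disease = GeneSet("A", "disease_A", frozenset({"U0"}))
        results = enrich(frozenset({"U1", "U2"}), disease, cat)
        t1 = next(r for r in results if r.term_id == "T1")
        assert t1.k == 0 and t1.p_value == 1.0

    def test_query_outside_universe_is_error(self):
        cat = _catalog([{"a", "b"}])
        disease = GeneSet("A", "disease_A", frozenset({"ZZZ"}))
        with pytest.raises(ValueError, match="universe"):
            enrich(frozenset({"YYY"}), disease, cat)

    def test_q_values_bound_p_values(self, synthetic_study):
        results = enrich(
            synthetic_study["truth"].modules[0],
            synthetic_study["genes_a"],
            synthetic_study["catalog"],
        )
        for r in results:
            assert r.q_value >= r.p_value - 1e-12
            assert 0 <= r.k <= min(r.n, r.M)


class TestFunctionalConsistency:
    def _results_with(self, hits, significant=True):
        from ppdt.enrichment import EnrichmentResult

        return [
            EnrichmentResult(
                term_id="T0", category="BP", N=100, n=10, M=10, k=len(hits),
                p_value=0.001, q_value=0.001 if significant else 0.9,
                significant=significant, hit_genes=frozenset(hits),
            )
        ]

    def test_shared_significant_term_passes(self):
        module = _candidate({"M1", "M2"})
        disease = GeneSet("A", "disease_A", frozenset({"D1"}))
        results = self._results_with({"M1", "D1"})
        assert functional_consistency(module, results, disease)

    def test_no_significant_term_fails(self):
        module = _candidate({"M1"})
        disease = GeneSet("A", "disease_A", frozenset({"D1"}))
        results = self._results_with({"M1", "D1"}, significant=False)
        assert not functional_consistency(module, results, disease)

    def test_terms_hit_only_by_disease_genes_fail(self):
        module = _candidate({"M1"})
        disease = GeneSet("A", "disease_A", frozenset({"D1", "D2"}))
        results = self._results_with({"D1", "D2"})
        assert not functional_consistency(module, results, disease)


class TestSelectTargets:
    def _table(self, n):
        genes = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame({"g_rank": np.arange(1, n + 1)}, index=genes)

    def _sig(self, hits):
        from ppdt.enrichment import EnrichmentResult

        return [
            EnrichmentResult(
                term_id="T0", category="BP", N=500, n=50, M=40, k=len(hits),
                p_value=1e-8, q_value=1e-7, significant=True,
                hit_genes=frozenset(hits),
            )
        ]

    def test_cutoff_is_ceil_n_over_4(self):
        table = self._table(85)
        sel = select_targets(table, self._sig(set(table.index)))
        assert sel.cutoff_rank == 22
        assert len(sel.selected) == 22

    def test_small_module_cutoff(self):
        table = self._table(4)
        sel = select_targets(table, self._sig(set(table.index)))
        assert sel.cutoff_rank == 1 and len(sel.selected) == 1

    def test_top_gene_without_term_support_excluded(self):
        table = self._table(8)  # cutoff 2
        sel = select_targets(table, self._sig({"g001"}))  # rank-1 gene g000 unsupported
        assert sel.selected == ("g001",)

    def test_never_more_than_quartile(self):
        for n in (3, 10, 17, 85):
            table = self._table(n)
            sel = select_targets(table, self._sig(set(table.index)))
            assert len(sel.selected) <= math.ceil(n / 4)
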