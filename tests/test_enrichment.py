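import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from gliaprot.enrichment import (EnrichmentResult, SimilarityConfig, enrich,
                                 hierarchy_rollup, hypergeom_pmf,
                                 hypergeom_tail, significant, simplify_terms,
                                 wang_similarity)
from gliaprot.io import GeneSetCollection, OntologyDAG, Relation
from .oracles import enumerated_tail


class TestHypergeomCore:
    def test_tail_examples_from_enumeration(self):
        assert hypergeom_tail(3, 10, 5, 4, "over") == pytest.approx(55 / 210, abs=1e-12)
        assert hypergeom_tail(0, 10, 5, 4, "under") == pytest.approx(5 / 210, abs=1e-12)

    def test_over_tail_at_zero_is_one(self, rng):
        for _ in range(20):
            N = int(rng.integers(1, 40))
            K, n = int(rng.integers(0, N + 1)), int(rng.integers(0, N + 1))
            assert hypergeom_tail(0, N, K, n, "over") == 1.0

    def test_matches_enumeration_small(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(n + 2):
                        for d in ("over", "under"):
                            exact = float(enumerated_tail(N, K, n, k, d))
                            assert hypergeom_tail(k, N, K, n, d) == pytest.approx(
                                exact, abs=1e-12), (N, K, n, k, d)

    def test_matches_fisher_exact(self, rng):
        for _ in range(150):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            assert hypergeom_tail(k, N, K, n, "over") == pytest.approx(
                fisher_exact(table, alternative="greater")[1], abs=1e-10)
            assert hypergeom_tail(k, N, K, n, "under") == pytest.approx(
                fisher_exact(table, alternative="less")[1], abs=1e-10)

    def test_pmf_normalizes(self, rng):
        for N in [1, 2, 7, 40, 120, 200]:
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            total = sum(hypergeom_pmf(k, N, K, n) for k in range(n + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tail_duality_hypothesis(self, data):
        N = data.draw(st.integers(1, 150))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(1, n + 1))
        over = hypergeom_tail(k, N, K, n, "over")
        under = hypergeom_tail(k - 1, N, K, n, "under")
        assert over + under == pytest.approx(1.0, abs=1e-12)

    def test_tail_duality(self, rng):
        for _ in range(50):
            N = int(rng.integers(1, 100))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(1, n + 2))
            over = hypergeom_tail(k, N, K, n, "over")
            under = hypergeom_tail(k - 1, N, K, n, "under")
            assert over + under == pytest.approx(1.0, abs=1e-12)

    def test_never_nan_and_clamped(self):
        for k, N, K, n in [(5, 10, 0, 10), (0, 1, 1, 0), (3, 3, 3, 3)]:
            for d in ("over", "under"):
                p = hypergeom_tail(k, N, K, n, d)
                assert 0.0 <= p <= 1.0 and not math.isnan(p)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(1, 10, 11, 5)
        with pytest.raises(ValueError):
            hypergeom_pmf(1, 10, 5, 11)
        with pytest.raises(ValueError):
            hypergeom_tail(1.5, 10, 5, 5)


def _annotation(sets: dict[str, set[str]]) -> GeneSetCollection:
    coll = GeneSetCollection()
    for tid, members in sets.items():
        coll.add(tid, tid.lower(), members)
    return coll


class TestEnrich:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g10"}
        res = enrich(query, universe, _annotation({"T": term}))
        (r,) = res
        assert (r.k, r.n, r.K, r.N) == (3, 4, 5, 20)
        assert r.fold_change == pytest.approx(3.0)
        # P(X >= 3) = (C(5,3)C(15,1) + C(5,4)C(15,0)) / C(20,4) = 155/4845
        exact = float(enumerated_tail(20, 5, 4, 3, "over"))
        assert exact == pytest.approx(155 / 4845, abs=1e-15)
        assert r.p_raw == pytest.approx(exact, abs=1e-12)
        assert r.p_adj == pytest.approx(exact, abs=1e-12)  # m = 1

    def test_query_equals_background(self):
        universe = {f"g{i}" for i in range(12)}
        res = enrich(universe, universe, _annotation({"T": {"g0", "g1", "g2"}}))
        (r,) = res
        assert r.fold_change == pytest.approx(1.0)
        assert r.p_raw == 1.0

    def test_bonferroni_clamped(self):
        # three tested terms, each with a middling p: m * p exceeds 1
        universe = {f"g{i}" for i in range(10)}
        sets = {f"T{j}": {f"g{j}", f"g{j+1}"} for j in range(3)}
        res = enrich({"g9"}, universe, _annotation(sets))
        assert all(r.p_adj == 1.0 for r in res if r.p_raw > 1 / 3)
        assert all(r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw)) for r in res)

    def test_terms_outside_background_not_counted(self):
        universe = {"g1", "g2"}
        sets = {"T1": {"g1"}, "T2": {"x1", "x2"}}  # T2 has K = 0 after intersection
        res = enrich({"g1"}, universe, _annotation(sets))
        assert [r.term_id for r in res] == ["T1"]
        assert res[0].p_adj == res[0].p_raw  # m = 1, not 2

    def test_query_outside_background_dropped(self, caplog):
        import logging
        universe = {"g1", "g2", "g3"}
        with caplog.at_level(logging.INFO):
            res = enrich({"g1", "zz"}, universe, _annotation({"T": {"g1"}}))
        assert res[0].n == 1
        assert "dropped 1" in caplog.text

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich({"zz"}, {"g1"}, _annotation({"T": {"g1"}}))

    def test_bh_correction_available(self):
        universe = {f"g{i}" for i in range(30)}
        sets = {f"T{j}": {f"g{k}" for k in range(j, j + 5)} for j in range(4)}
        res = enrich({"g0", "g1", "g2"}, universe, _annotation(sets), correction="bh")
        assert all(r.p_adj >= r.p_raw - 1e-12 for r in res)


class TestSignificant:
    def _result(self, fold, p_adj, direction="over"):
        return EnrichmentResult("T", "t", 1, 10, 5, 100, fold, min(p_adj, p_adj),
                                p_adj, direction)

    @pytest.mark.parametrize("fold,p_adj,kept", [
        (1.5, 0.005, False),   # fold must be strictly greater
        (2.0, 0.01, False),    # p_adj must be strictly smaller
        (2.0, 0.005, True),
    ])
    def test_strict_filters(self, fold, p_adj, kept):
        res = [self._result(fold, p_adj)]
        assert (len(significant(res)) == 1) is kept

    def test_under_direction_flips_fold(self):
        depleted = self._result(0.5, 0.001, direction="under")
        not_depleted = self._result(0.7, 0.001, direction="under")
        assert significant([depleted, not_depleted]) == [depleted]


def _two_term_dag() -> OntologyDAG:
    dag = OntologyDAG()
    dag.add_term("A", "a", "ns")
    dag.add_term("B", "b", "ns")
    dag.add_edge("B", "A", Relation.IS_A)
    dag.validate()
    return dag


class TestWangSimilarity:
    def test_identity(self, chain_dag):
        assert wang_similarity("T", "T", chain_dag) == 1.0

    def test_single_is_a_edge(self):
        # S-values: B {B:1, A:0.8} -> SV 1.8; A {A:1} -> SV 1.0; shared {A}
        dag = _two_term_dag()
        assert wang_similarity("A", "B", dag) == pytest.approx((1.0 + 0.8) / 2.8)

    def test_disjoint_roots_zero(self):
        dag = OntologyDAG()
        for t in ("A", "B"):
            dag.add_term(t, t, f"ns_{t}")
        assert wang_similarity("A", "B", dag) == 0.0

    def test_part_of_weight(self):
        dag = OntologyDAG()
        dag.add_term("A", "a", "ns")
        dag.add_term("B", "b", "ns")
        dag.add_edge("B", "A", Relation.PART_OF)
        assert wang_similarity("A", "B", dag) == pytest.approx((1.0 + 0.6) / 2.6)

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            wang_similarity("T", "nope", chain_dag)

    def test_symmetric_and_bounded(self, chain_dag):
        terms = list(chain_dag.terms)
        for a in terms:
            for b in terms:
                s = wang_similarity(a, b, chain_dag)
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(wang_similarity(b, a, chain_dag))


def _chain_results(p_adjs: dict[str, float]) -> list[EnrichmentResult]:
    return [EnrichmentResult(t, t.lower(), 2, 10, 5, 100, 4.0, p, p, "over")
            for t, p in p_adjs.items()]


class TestSimplifyTerms:
    def _dag_with_sims(self):
        # A and B share a deep chain (similar); C hangs off the root (dissimilar)
        dag = OntologyDAG()
        for t in ("root", "mid1", "mid2", "A", "B", "C"):
            dag.add_term(t, t, "ns")
        dag.add_edge("mid1", "root")
        dag.add_edge("mid2", "mid1")
        dag.add_edge("A", "mid2")
        dag.add_edge("B", "mid2")
        dag.add_edge("C", "root")
        dag.validate()
        return dag

    def test_redundant_pair_drops_worse_p(self):
        # wang sims here: A-B 0.661, A-C = B-C 0.276; cutoff between them
        dag = self._dag_with_sims()
        res = _chain_results({"A": 0.001, "B": 0.005, "C": 0.002})
        kept = simplify_terms(res, dag, SimilarityConfig(cutoff=0.5))
        assert {r.term_id for r in kept} == {"A", "C"}

    def test_no_pair_above_cutoff_is_fixed_point(self):
        dag = self._dag_with_sims()
        res = _chain_results({"A": 0.001, "C": 0.002})
        cfg = SimilarityConfig(cutoff=0.99)
        assert simplify_terms(res, dag, cfg) == res

    def test_chain_keeps_ends(self):
        # pairwise sims: A-B and B-C high, A-C low; dropping B resolves both
        dag = OntologyDAG()
        for t in ("root", "hubAB", "hubBC", "A", "B", "C"):
            dag.add_term(t, t, "ns")
        dag.add_edge("hubAB", "root")
        dag.add_edge("hubBC", "root")
        dag.add_edge("A", "hubAB")
        dag.add_edge("B", "hubAB")
        dag.add_edge("B", "hubBC")
        dag.add_edge("C", "hubBC")
        dag.validate()
        sim_ab = wang_similarity("A", "B", dag)
        sim_ac = wang_similarity("A", "C", dag)
        cfg = SimilarityConfig(cutoff=(sim_ab + sim_ac) / 2)
        res = _chain_results({"A": 0.001, "B": 0.002, "C": 0.003})
        kept = simplify_terms(res, dag, cfg)
        assert {r.term_id for r in kept} == {"A", "C"}

    def test_idempotent(self):
        dag = self._dag_with_sims()
        res = _chain_results({"A": 0.001, "B": 0.005, "C": 0.002})
        cfg = SimilarityConfig(cutoff=0.5)
        once = simplify_terms(res, dag, cfg)
        assert simplify_terms(once, dag, cfg) == once

    def test_no_retained_pair_exceeds_cutoff(self):
        dag = self._dag_with_sims()
        cfg = SimilarityConfig(cutoff=0.3)
        kept = simplify_terms(_chain_results({"A": 0.01, "B": 0.02, "C": 0.03}), dag, cfg)
        ids = [r.term_id for r in kept]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert wang_similarity(a, b, dag, cfg) <= cfg.cutoff


class TestHierarchyRollup:
    def test_chain(self, chain_dag):
        res = _chain_results({"T": 0.001})
        (_, pairs), = hierarchy_rollup(res, chain_dag)
        assert pairs == [("R", "P1")]

    def test_root_maps_to_itself(self, chain_dag):
        (_, pairs), = hierarchy_rollup(_chain_results({"R": 0.001}), chain_dag)
        assert pairs == [("R", "R")]

    def test_diamond_gives_both_subpathways(self):
        dag = OntologyDAG()
        for t in ("R", "S1", "S2", "T"):
            dag.add_term(t, t, "ns")
        dag.add_edge("S1", "R")
        dag.add_edge("S2", "R")
        dag.add_edge("T", "S1")
        dag.add_edge("T", "S2")
        dag.validate()
        (_, pairs), = hierarchy_rollup(_chain_results({"T": 0.001}), dag)
        assert pairs == [("R", "S1"), ("R", "S2")]

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            hierarchy_rollup(_chain_results({"missing": 0.01}), chain_dag)
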