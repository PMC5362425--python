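"""Hypergeometric enrichment, BH correction, and kappa term grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from netpharm import (
    GeneSetCollection,
    GeneSetTerm,
    hypergeom_enrich,
    hypergeom_pvalue,
    kappa_group_terms,
    kappa_statistic,
)
from oracles import bh_stepup, exact_hypergeom_tail

GENES = [f"G{i:03d}" for i in range(100)]


def collection(*terms):
    coll = GeneSetCollection()
    for tid, genes, cat in terms:
        coll.add(GeneSetTerm(tid, tid, cat, frozenset(genes)))
    return coll


class TestHypergeomP:
    def test_worked_example(self):
        # N=20, K=5, n=10, k=5: only the single term C(15,5)/C(20,10)
        assert hypergeom_pvalue(5, 5, 10, 20) == pytest.approx(3003 / 184756, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_pvalue(0, 5, 10, 20) == 1.0

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(data=st.data())
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(1, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        expected = float(exact_hypergeom_tail(k, K, n, N))
        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(expected, abs=1e-12)


class TestEnrich:
    def test_bh_stepup_hand_case(self):
        # the step-up rule collapses {0.01, 0.02, 0.03} to {0.03, 0.03, 0.03}
        assert bh_stepup([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        universe = set(GENES[:20])
        query = set(GENES[:10])
        # construct terms whose raw p are ordered but distinct
        coll = collection(
            ("T1", GENES[:5], "other"),
            ("T2", GENES[2:8], "other"),
            ("T3", GENES[5:11], "other"),
        )
        results = hypergeom_enrich(query, coll, universe)
        raws = [r.p for r in results]
        adj = {r.term_id: r.p_adj for r in results}
        expected = dict(zip([r.term_id for r in results], bh_stepup(raws)))
        for tid in adj:
            assert adj[tid] == pytest.approx(expected[tid], abs=1e-12)

    def test_bh_within_category_separately(self):
        universe = set(GENES[:40])
        query = set(GENES[:10])
        coll = collection(
            ("A1", GENES[:8], "signaling_pathway"),
            ("A2", GENES[20:30], "signaling_pathway"),
            ("B1", GENES[:8], "molecular_function_biological_process"),
        )
        split = hypergeom_enrich(query, coll, universe, by_category=True)
        # identical term in each category gets m=2 vs m=1 families
        p_a1 = next(r for r in split if r.term_id == "A1")
        p_b1 = next(r for r in split if r.term_id == "B1")
        assert p_a1.p == p_b1.p
        assert p_b1.p_adj == pytest.approx(p_b1.p, abs=1e-15)

    def test_counts_and_invariants(self):
        universe = set(GENES[:50])
        query = set(GENES[:12])
        coll = collection(("T1", GENES[8:20], "other"), ("T2", GENES[45:60], "other"))
        results = {r.term_id: r for r in hypergeom_enrich(query, coll, universe)}
        t1 = results["T1"]
        assert (t1.N, t1.n, t1.K, t1.k) == (50, 12, 12, 4)
        t2 = results["T2"]
        assert t2.K == 5  # restricted to the universe
        for r in results.values():
            assert r.p <= r.p_adj <= 1.0

    def test_query_outside_universe_dropped(self, caplog):
        universe = set(GENES[:20])
        coll = collection(("T1", GENES[:5], "other"))
        results = hypergeom_enrich(set(GENES[:10]) | {"ALIEN"}, coll, universe)
        assert results[0].n == 10

    def test_term_with_no_universe_genes_skipped(self):
        universe = set(GENES[:20])
        coll = collection(("T1", GENES[:5], "other"), ("T2", GENES[90:], "other"))
        assert [r.term_id for r in hypergeom_enrich(set(GENES[:5]), coll, universe)] == ["T1"]

    def test_universe_smaller_than_query_is_error(self):
        coll = collection(("T1", GENES[:5], "other"))
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich(set(GENES[:30]), coll, set(GENES[:10]))

    def test_empty_universe_is_error(self):
        coll = collection(("T1", GENES[:5], "other"))
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), coll, set())


class TestKappa:
    REF = frozenset(GENES)

    def test_identical_sets_give_one(self):
        s = frozenset(GENES[:10])
        assert kappa_statistic(s, s, self.REF) == 1.0

    def test_worked_2x2_table(self):
        # a=10 shared, b=c=5 each-only, d=80 -> po=0.90, pe=0.745, kappa~0.6078
        a = frozenset(GENES[:15])  # 10 shared + 5 own
        b = frozenset(GENES[:10] + GENES[15:20])
        kappa = kappa_statistic(a, b, self.REF)
        assert kappa == pytest.approx((0.90 - 0.745) / (1 - 0.745), abs=1e-12)
        assert kappa == pytest.approx(0.6078, abs=1e-4)

    def test_disjoint_sets_negative(self):
        a = frozenset(GENES[:15])
        b = frozenset(GENES[15:30])
        assert kappa_statistic(a, b, self.REF) < 0

    def test_symmetry_and_relabel_invariance(self):
        a, b = frozenset(GENES[:12]), frozenset(GENES[6:20])
        assert kappa_statistic(a, b, self.REF) == kappa_statistic(b, a, self.REF)
        relabel = {g: f"X{g}" for g in GENES}
        ka = kappa_statistic(
            frozenset(relabel[g] for g in a),
            frozenset(relabel[g] for g in b),
            frozenset(relabel.values()),
        )
        assert ka == pytest.approx(kappa_statistic(a, b, self.REF), abs=1e-12)

    def test_degenerate_full_agreement(self):
        assert kappa_statistic(self.REF, self.REF, self.REF) == 1.0


class TestGrouping:
    def _enrich(self, coll, query, universe):
        return [r for r in hypergeom_enrich(query, coll, universe) if r.enriched]

    def test_identical_terms_grouped_with_leading_term(self):
        universe = set(GENES[:60])
        query = set(GENES[:10])
        coll = collection(
            ("T1", GENES[:10], "other"),
            ("T2", GENES[:10], "other"),
            ("T9", GENES[40:55], "other"),
        )
        enriched = self._enrich(coll, query, universe)
        groups = kappa_group_terms(enriched, coll, universe)
        linked = next(g for g in groups if len(g.members) > 1)
        assert set(linked.members) == {"T1", "T2"}
        assert linked.leading_term == "T1"  # tie on p_adj -> lexicographic
        assert all(k >= 0.4 for _, _, k in linked.links)

    def test_disjoint_terms_stay_singletons(self):
        universe = set(GENES)
        query = set(GENES[:20])
        coll = collection(
            ("T1", GENES[:15], "other"),
            ("T2", GENES[15:30], "other"),
        )
        enriched = self._enrich(coll, query, universe)
        groups = kappa_group_terms(enriched, coll, universe)
        assert all(len(g.members) == 1 for g in groups)

    def test_empty_results_give_empty_groups(self):
        coll = collection(("T1", GENES[:5], "other"))
        assert kappa_group_terms([], coll, set(GENES)) == []
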