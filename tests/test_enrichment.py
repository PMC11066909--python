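"""GSEA, ORA, ssGSEA and semantic-similarity checks against brute-force oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rosette_omics.core_io import GeneSet, GeneSetCollection, OntologyDAG, ValidationError
from rosette_omics.differential import RankedList
from rosette_omics.enrichment import (
    bh_adjust,
    enrichment_score,
    gsea_preranked,
    ora_hypergeometric,
    redundancy_filter,
    ssgsea_score,
    term_similarity,
)
from rosette_omics.simulate import generate_ontology


def brute_force_es(ranked: RankedList, members, weight: float) -> float:
    """Independent oracle: walk the full running sum and take its extremum."""
    n = len(ranked)
    hits = [g in members for g in ranked.genes]
    k = sum(hits)
    nr = sum(abs(s) ** weight for s, h in zip(ranked.scores, hits) if h)
    uniform = nr <= 0
    run, run_max, run_min = 0.0, 0.0, 0.0
    for s, h in zip(ranked.scores, hits):
        if h:
            run += (1.0 / k) if uniform else abs(s) ** weight / nr
        elif n > k:
            run -= 1.0 / (n - k)
        run_max = max(run_max, run)
        run_min = min(run_min, run)
    # on a |tie| (within fp tolerance) the positive extremum wins
    return run_max if run_max + run_min >= -1e-12 else run_min


def _random_ranked(rng, n=20):
    genes = [f"g{i:02d}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    scores += np.linspace(0, 1e-9, n)[::-1]  # make strictly decreasing
    return RankedList(genes, scores)


class TestEnrichmentScore:
    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_brute_force_on_random_lists(self, weight):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ranked = _random_ranked(rng)
            members = frozenset(rng.choice(ranked.genes, size=5, replace=False))
            es, _ = enrichment_score(ranked, members, weight)
            assert es == pytest.approx(brute_force_es(ranked, members, weight), abs=1e-12)

    def test_top_k_set_at_weight_zero_reaches_unity(self):
        # hits occupy the first K positions: the unweighted running sum tops
        # out at K/K - 0 = 1 before any miss is paid
        ranked = _random_ranked(np.random.default_rng(1), n=10)
        members = frozenset(ranked.genes[:3])
        es, leading = enrichment_score(ranked, members, weight=0.0)
        assert es == pytest.approx(1.0)
        assert set(leading) == set(ranked.genes[:3])

    def test_spread_set_scores_below_top_set(self):
        ranked = _random_ranked(np.random.default_rng(2), n=21)
        spread = frozenset(ranked.genes[3::7])
        top = frozenset(ranked.genes[:3])
        es_spread, _ = enrichment_score(ranked, spread, 0.0)
        es_top, _ = enrichment_score(ranked, top, 0.0)
        assert abs(es_spread) < abs(es_top)
        assert abs(es_spread) < 0.5

    def test_sign_equivariance_under_score_negation(self):
        ranked = _random_ranked(np.random.default_rng(3))
        members = frozenset(ranked.genes[:4])
        es, _ = enrichment_score(ranked, members, 1.0)
        flipped = RankedList(ranked.genes[::-1], -ranked.scores[::-1])
        es_neg, _ = enrichment_score(flipped, members, 1.0)
        assert es_neg == pytest.approx(-es, abs=1e-12)

    def test_weight_zero_invariant_to_monotone_rescaling(self):
        ranked = _random_ranked(np.random.default_rng(4))
        members = frozenset(ranked.genes[5:10])
        es1, _ = enrichment_score(ranked, members, 0.0)
        rescaled = RankedList(ranked.genes, np.exp(ranked.scores))
        es2, _ = enrichment_score(rescaled, members, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_magnitude_bounded_by_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ranked = _random_ranked(rng, n=15)
            members = frozenset(rng.choice(ranked.genes, size=6, replace=False))
            es, _ = enrichment_score(ranked, members, 1.0)
            assert abs(es) <= 1.0 + 1e-12

    def test_no_overlap_rejected(self):
        ranked = _random_ranked(np.random.default_rng(6))
        with pytest.raises(ValidationError):
            enrichment_score(ranked, frozenset({"absent"}), 1.0)


class TestGseaPreranked:
    def _collection(self, ranked, rng, n_sets=5, size=3):
        sets = [
            GeneSet(f"S{j}", "", frozenset(rng.choice(ranked.genes, size=size, replace=False)))
            for j in range(n_sets)
        ]
        return GeneSetCollection(sets)

    def test_permutation_p_matches_full_enumeration(self):
        """On an 8-gene list with a 3-gene set, the sampled membership null
        must agree with exhaustive enumeration of all C(8,3) memberships."""
        rng = np.random.default_rng(7)
        ranked = _random_ranked(rng, n=8)
        members = frozenset(ranked.genes[:3])
        sets = GeneSetCollection([GeneSet("S", "", members)])
        res = gsea_preranked(ranked, sets, min_size=3, max_size=8, weight=1.0,
                             n_perm=4000, seed=1)
        es = res.loc["S", "es"]
        null = [
            brute_force_es(ranked, frozenset(c), 1.0)
            for c in combinations(ranked.genes, 3)
        ]
        same = [e for e in null if (e >= 0) == (es >= 0)]
        exact = sum(abs(e) >= abs(es) - 1e-12 for e in same) / len(same)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.loc["S", "p"] - exact) <= 2 * se + 2 / 4000

    def test_same_seed_reproduces_bitwise(self):
        rng = np.random.default_rng(8)
        ranked = _random_ranked(rng, n=30)
        sets = self._collection(ranked, rng, size=6)
        r1 = gsea_preranked(ranked, sets, min_size=3, max_size=30, n_perm=200, seed=5)
        r2 = gsea_preranked(ranked, sets, min_size=3, max_size=30, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_result_invariants(self):
        rng = np.random.default_rng(9)
        ranked = _random_ranked(rng, n=40)
        sets = self._collection(ranked, rng, n_sets=8, size=8)
        res = gsea_preranked(ranked, sets, min_size=3, max_size=40, n_perm=200, seed=3)
        assert (res["es"].abs() <= 1.0 + 1e-12).all()
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_planted_top_set_is_most_significant(self):
        rng = np.random.default_rng(10)
        ranked = _random_ranked(rng, n=60)
        planted = GeneSet("PLANTED", "", frozenset(ranked.genes[:10]))
        background = [
            GeneSet(f"BG{j}", "", frozenset(rng.choice(ranked.genes, 10, replace=False)))
            for j in range(6)
        ]
        res = gsea_preranked(
            RankedList(ranked.genes, np.linspace(3, -3, 60)),
            GeneSetCollection([planted, *background]),
            min_size=5, max_size=60, n_perm=500, seed=2,
        )
        assert res.index[0] == "PLANTED"
        assert res.loc["PLANTED", "nes"] > 0

    def test_guards(self):
        rng = np.random.default_rng(11)
        ranked = _random_ranked(rng)
        sets = self._collection(ranked, rng)
        with pytest.raises(ValidationError):
            gsea_preranked(ranked, sets, n_perm=50, seed=1)
        with pytest.raises(ValidationError):
            gsea_preranked(ranked, sets, n_perm=200, seed=None)
        off_list = GeneSetCollection([GeneSet("X", "", frozenset({"missing"}))])
        with pytest.raises(ValidationError):
            gsea_preranked(ranked, off_list, min_size=1, max_size=5, n_perm=200, seed=1)


def exact_upper_tail(N, K, n, k):
    """Hypergeometric P(X >= k) by direct combinatorial enumeration."""
    from math import comb

    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


class TestOra:
    def _run(self, hits, universe, members, **kw):
        sets = GeneSetCollection([GeneSet("S", "", frozenset(members))])
        return ora_hypergeometric(set(hits), set(universe), sets,
                                  min_size=1, max_size=1000, **kw)

    def test_worked_example_matches_enumeration(self):
        universe = [f"u{i}" for i in range(20)]
        members = universe[:5]
        hits = universe[:5] + universe[10:15]
        res = self._run(hits, universe, members)
        assert res.loc["S", "p"] == pytest.approx(exact_upper_tail(20, 5, 10, 5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_configurations_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 31))
        universe = [f"u{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        members = list(rng.choice(universe, K, replace=False))
        hits = list(rng.choice(universe, n, replace=False))
        res = self._run(hits, universe, members)
        k = len(set(members) & set(hits))
        assert res.loc["S", "k"] == k
        assert res.loc["S", "p"] == pytest.approx(exact_upper_tail(N, K, n, k), abs=1e-10)

    def test_count_rule_boundary(self):
        # p < .05 alone is not enough: the overlap must exceed 4 proteins
        universe = [f"u{i}" for i in range(1000)]
        members5 = universe[:5]
        res5 = self._run(universe[:5], universe, members5)
        assert res5.loc["S", "k"] == 5 and res5.loc["S", "over_represented"]
        members4 = universe[:4]
        res4 = self._run(universe[:4], universe, members4)
        assert res4.loc["S", "k"] == 4 and res4.loc["S", "p"] < 0.001
        assert not res4.loc["S", "over_represented"]

    def test_hits_equal_universe_gives_p_one(self):
        universe = [f"u{i}" for i in range(12)]
        res = self._run(universe, universe, universe[:6])
        assert res.loc["S", "k"] == 6
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            self._run(["x"], ["a", "b"], ["a"])


class TestSsgsea:
    def test_full_set_scores_zero(self):
        values = {f"g{i}": float(i) for i in range(10)}
        assert ssgsea_score(values, frozenset(values)) == 0.0

    def test_top_gene_beats_bottom_gene(self):
        values = {f"g{i}": float(i) for i in range(10)}
        top = ssgsea_score(values, frozenset({"g9"}))
        bottom = ssgsea_score(values, frozenset({"g0"}))
        assert top > bottom

    def test_toy_example_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=10))}
        members = frozenset(["g1", "g4", "g7"])
        # oracle: literal definition, gene by gene
        ordered = sorted(values, key=lambda g: (-values[g], g))
        n = len(ordered)
        ranks = {g: n - i for i, g in enumerate(ordered)}
        denom = sum(ranks[g] ** 0.25 for g in ordered if g in members)
        p_in = p_out = 0.0
        expected = 0.0
        for g in ordered:
            if g in members:
                p_in += ranks[g] ** 0.25 / denom
            else:
                p_out += 1.0 / (n - len(members))
            expected += p_in - p_out
        assert ssgsea_score(values, members) == pytest.approx(expected, abs=1e-12)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            ssgsea_score({"a": 1.0}, frozenset({"zzz"}))


def _toy_dag():
    """R <- A <- {B, C}; R <- D.  Annotation counts fixed by hand."""
    g = nx.DiGraph()
    for t in ("R", "A", "B", "C", "D"):
        g.add_node(t, name=t, namespace="bp")
    g.add_edge("A", "R")
    g.add_edge("B", "A")
    g.add_edge("C", "A")
    g.add_edge("D", "R")
    ann = {"B": {"g1", "g2"}, "C": {"g2", "g3"}, "D": {"g4", "g5", "g6"}}
    return OntologyDAG(g, ann)


class TestTermSimilarity:
    def test_hand_computed_toy(self):
        dag = _toy_dag()
        # propagated: A={g1,g2,g3}, R=all 6; IC(A)=ln(2), IC(B)=IC(C)=ln(3)
        resnik, lin = term_similarity(dag, "B", "C")
        max_ic = np.log(6 / 2)  # IC of B/C/D... D has 3 genes -> ln(2); B has 2 -> ln(3)
        assert resnik == pytest.approx(np.log(6 / 3) / np.log(6 / 2))
        assert lin == pytest.approx(2 * np.log(2) / (2 * np.log(3)))

    def test_self_similarity_of_non_root_is_one(self):
        dag = _toy_dag()
        _, lin = term_similarity(dag, "B", "B")
        assert lin == pytest.approx(1.0)

    def test_root_mica_gives_zero(self):
        dag = _toy_dag()
        resnik, lin = term_similarity(dag, "B", "D")
        assert resnik == 0.0 and lin == 0.0

    def test_namespace_mismatch_rejected(self):
        g = nx.DiGraph()
        g.add_node("R1", namespace="bp")
        g.add_node("R2", namespace="mf")
        dag = OntologyDAG(g, {"R1": {"a"}, "R2": {"b"}})
        with pytest.raises(ValidationError):
            term_similarity(dag, "R1", "R2")

    def test_unannotated_term_rejected(self):
        g = nx.DiGraph()
        g.add_node("R", namespace="bp")
        g.add_node("T", namespace="bp")
        g.add_edge("T", "R")
        dag = OntologyDAG(g, {"R": {"a"}})
        with pytest.raises(ValidationError):
            term_similarity(dag, "T", "T")


class TestRedundancyFilter:
    def test_identical_annotation_keeps_more_significant(self):
        g = nx.DiGraph()
        for t in ("R", "P", "T1", "T2"):
            g.add_node(t, namespace="bp")
        g.add_edge("P", "R")
        g.add_edge("T1", "P")
        g.add_edge("T2", "P")
        g.add_node("Q", namespace="bp")
        g.add_edge("Q", "R")
        dag = OntologyDAG(g, {"T1": {"a", "b"}, "T2": {"a", "b"}, "Q": {"c", "d", "e"}})
        results = pd.DataFrame({"p": [0.04, 0.001]}, index=["T1", "T2"])
        out = redundancy_filter(results, dag)
        assert list(out.index) == ["T2"]

    def test_planted_redundant_pair_has_one_survivor(self, small_ontology):
        a, b = small_ontology.graph.graph["redundant_pair"]
        results = pd.DataFrame({"p": [0.01, 0.02]}, index=[a, b])
        out = redundancy_filter(results, small_ontology)
        assert list(out.index) == [a]

    def test_dissimilar_terms_pass_unfiltered(self):
        dag = _toy_dag()
        results = pd.DataFrame({"p": [0.01, 0.02]}, index=["B", "D"])  # root MICA
        out = redundancy_filter(results, dag)
        assert set(out.index) == {"B", "D"}


class TestBhAdjust:
    def test_monotone_in_nominal_p(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        q = bh_adjust(p)
        m = len(p)
        expected = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(q, np.minimum(expected, 1.0), atol=1e-12)
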