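import itertools
import math

import numpy as np
import pytest

from chromtriad.enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    hypergeometric_ora,
    preranked_collection,
    preranked_es,
    preranked_significance,
    read_gmt,
    top_k,
    write_gmt,
)
from oracles import running_sum_bruteforce


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"SET_A": frozenset({"g1", "g2"}), "SET_B": frozenset({"g3"})}
        )
        f = tmp_path / "sets.gmt"
        write_gmt(coll, f)
        back = read_gmt(f)
        assert back.sets == coll.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection(sets={"S": frozenset()})

    def test_universe_containment_enforced(self):
        with pytest.raises(ValueError, match="outside the universe"):
            GeneSetCollection(
                sets={"S": frozenset({"a", "zz"})},
                universe=frozenset({"a", "b"}),
            )


def ora_p_enumeration(universe, gene_set, query):
    """P(overlap >= k) by enumerating every same-size query."""
    k = len(query & gene_set)
    n_hit = 0
    n_all = 0
    for q in itertools.combinations(sorted(universe), len(query)):
        n_all += 1
        if len(set(q) & gene_set) >= k:
            n_hit += 1
    return n_hit / n_all


class TestHypergeometricOra:
    def test_perfect_overlap_small_universe(self):
        universe = {f"g{i}" for i in range(10)}
        s = set(sorted(universe)[:5])
        res = hypergeometric_ora(s, s, universe)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_p_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = hypergeometric_ora(set(sorted(universe)[:3]),
                                 set(sorted(universe)[7:]), universe)
        assert res.p_value == pytest.approx(1.0)

    def test_query_equals_universe_forced(self):
        universe = {f"g{i}" for i in range(8)}
        s = set(sorted(universe)[:3])
        res = hypergeometric_ora(universe, s, universe)
        assert res.overlap == 3
        assert res.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(25):
            universe = set(genes[: int(rng.integers(5, 13))])
            pool = sorted(universe)
            s = set(rng.choice(pool, int(rng.integers(1, len(pool))),
                               replace=False))
            q = set(rng.choice(pool, int(rng.integers(1, len(pool))),
                               replace=False))
            res = hypergeometric_ora(q, s, universe)
            assert res.p_value == pytest.approx(
                ora_p_enumeration(universe, s, q), abs=1e-12
            )

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_ora(set(), set(), set())


def random_ranking(rng, n):
    scores = rng.normal(0, 1, n)
    return [(f"g{i}", float(s)) for i, s in enumerate(scores)]


class TestPrerankedES:
    def test_top_gene_singleton_set_unweighted(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        es, running = preranked_es(ranked, {"a"}, weight_p=0.0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_all_genes_in_set_is_degenerate_one(self):
        ranked = [("a", 2.0), ("b", 1.0), ("c", 0.5)]
        es, _ = preranked_es(ranked, {"a", "b", "c"})
        assert es == pytest.approx(1.0)

    def test_matches_stepwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            ranked = random_ranking(rng, n)
            size = int(rng.integers(1, n))
            members = set(
                rng.choice([g for g, _ in ranked], size, replace=False)
            )
            p = float(rng.choice([0.0, 1.0, 2.0]))
            es, running = preranked_es(ranked, members, weight_p=p)
            es_oracle, running_oracle = running_sum_bruteforce(
                ranked, members, p
            )
            assert es == pytest.approx(es_oracle)
            assert np.allclose(running, running_oracle)

    def test_scale_invariance_at_weight_one(self, rng):
        ranked = random_ranking(rng, 30)
        members = {g for g, _ in ranked[3:9]}
        es1, _ = preranked_es(ranked, members, weight_p=1.0)
        scaled = [(g, 7.5 * s) for g, s in ranked]
        es2, _ = preranked_es(scaled, members, weight_p=1.0)
        assert es1 == pytest.approx(es2)

    def test_matches_independent_gsea_implementation(self, rng):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        for trial in range(3):
            n = 60
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            members = list(rng.choice(genes, 9, replace=False))
            res = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": scores}),
                gene_sets={"S": members}, permutation_num=10, outdir=None,
                seed=1, weight=1.0, min_size=1, max_size=100, no_plot=True,
            )
            reference_es = float(res.res2d["ES"].iloc[0])
            es, _ = preranked_es(
                list(zip(genes, scores)), set(members), weight_p=1.0
            )
            assert es == pytest.approx(reference_es, abs=1e-6)

    def test_disjoint_set_is_error(self):
        with pytest.raises(ValueError, match="no genes"):
            preranked_es([("a", 1.0)], {"zzz"})

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            preranked_es([("a", 1.0), ("a", 0.5)], {"a"})


class TestPrerankedSignificance:
    def test_determinism_under_fixed_seed(self, rng):
        ranked = random_ranking(rng, 50)
        members = {g for g, _ in ranked[:6]}
        r1 = preranked_significance(ranked, members, n_perm=200, seed=42)
        r2 = preranked_significance(ranked, members, n_perm=200, seed=42)
        assert (r1.es, r1.nes, r1.p_value) == (r2.es, r2.nes, r2.p_value)

    def test_planted_top_set_attains_floor_p(self, rng):
        n = 100
        ranked = [(f"g{i}", float(n - i)) for i in range(n)]
        members = {f"g{i}" for i in range(8)}  # the eight top-ranked genes
        res = preranked_significance(ranked, members, n_perm=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.es > 0.9
        assert set(res.leading_edge) == members

    def test_leading_edge_for_negative_es(self):
        n = 40
        ranked = [(f"g{i}", float(n - i)) for i in range(n)]
        members = {f"g{i}" for i in range(n - 5, n)}  # bottom-ranked genes
        res = preranked_significance(ranked, members, n_perm=150, seed=0)
        assert res.es < 0
        assert set(res.leading_edge) <= members

    def test_collection_scoring_assigns_bh_q_values(self, rng):
        ranked = random_ranking(rng, 60)
        coll = GeneSetCollection(
            sets={
                "TOP": frozenset(
                    g for g, _ in sorted(ranked, key=lambda t: -t[1])[:6]
                ),
                "RAND1": frozenset(g for g, _ in ranked[10:16]),
                "RAND2": frozenset(g for g, _ in ranked[20:26]),
            }
        )
        results = preranked_collection(ranked, coll, n_perm=150, seed=3)
        assert len(results) == 3
        assert all(r.q_value is not None for r in results)
        best = min(results, key=lambda r: r.p_value)
        assert best.set_name == "TOP"


class TestTopK:
    def _res(self, name, p, nes):
        return EnrichmentResult(set_name=name, p_value=p, es=0.5, nes=nes)

    def test_fewer_results_than_k(self):
        rs = [self._res("a", 0.5, 1.0), self._res("b", 0.2, 1.0)]
        assert [r.set_name for r in top_k(rs, 10)] == ["b", "a"]

    def test_ties_break_by_nes_then_name(self):
        rs = [
            self._res("b", 0.1, 1.0),
            self._res("a", 0.1, 2.0),
            self._res("c", 0.1, 2.0),
        ]
        assert [r.set_name for r in top_k(rs, 3)] == ["a", "c", "b"]

    def test_k_one_picks_global_minimum(self):
        rs = [self._res(n, p, 1.0) for n, p in [("a", 0.3), ("b", 0.01), ("c", 0.2)]]
        assert top_k(rs, 1)[0].set_name == "b"
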