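import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from bpomics import (
    OntologyDAG,
    binary_cut,
    display_tables,
    gen_ontology,
    information_content,
    ora,
    prune_redundant,
    resnik,
    similarity_matrix,
)


@pytest.fixture
def chain_dag():
    """root -> a -> b with nested annotations (true-path rule by construction)."""
    return OntologyDAG.from_edges(
        [("a", "root"), ("b", "a")],
        {"root": {"g1", "g2", "g3", "g4"}, "a": {"g2", "g3"}, "b": {"g3"}},
    )


@pytest.fixture
def toy_dag():
    """Small multi-branch DAG over a 20-gene universe."""
    genes = [f"g{i}" for i in range(20)]
    return OntologyDAG.from_edges(
        [("immune", "root"), ("cycle", "root"), ("bcell", "immune"),
         ("neutro", "immune"), ("mitosis", "cycle"), ("dual", "immune"),
         ("dual", "cycle")],
        {
            "root": set(genes),
            "immune": set(genes[:8]),
            "bcell": set(genes[:4]),
            "neutro": set(genes[4:8]),
            "cycle": set(genes[8:16]),
            "mitosis": set(genes[8:12]),
            "dual": set(genes[6:10]),
        },
    )


class TestOntologyDAG:
    def test_true_path_closure_from_direct_annotations(self):
        dag = OntologyDAG.from_edges(
            [("a", "root"), ("b", "a")], {"b": {"x"}, "a": {"y"}, "root": set()}
        )
        assert dag.annotations["b"] == {"x"}
        assert dag.annotations["a"] == {"x", "y"}
        assert dag.annotations["root"] == {"x", "y"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            OntologyDAG.from_edges([("a", "b"), ("b", "a")], {})

    def test_chain_containment(self, chain_dag):
        assert chain_dag.annotations["b"] <= chain_dag.annotations["a"]
        assert chain_dag.annotations["a"] <= chain_dag.annotations["root"]


class TestInformationContent:
    def test_root_zero_and_half_corpus(self, chain_dag):
        ic = information_content(chain_dag)
        assert ic["root"] == 0.0
        assert math.isclose(ic["a"], math.log(2))  # 2 of 4 genes
        assert math.isclose(ic["b"], math.log(4))

    def test_monotone_along_edges(self):
        dag, _ = gen_ontology(25, n_genes=60, seed=7)
        ic = information_content(dag)
        for child, parent in dag.graph.edges:
            if child in ic and parent in ic:
                assert ic[child] >= ic[parent] - 1e-12


class TestResnik:
    def test_self_similarity_is_normalized_ic(self, chain_dag):
        ic = information_content(chain_dag)
        max_ic = max(ic.values())
        assert math.isclose(resnik(chain_dag, "b", "b"), ic["b"] / max_ic)

    def test_siblings_under_root_score_zero(self, toy_dag):
        assert resnik(toy_dag, "immune", "cycle") == 0.0

    def test_matches_exhaustive_ancestor_scan(self):
        dag, _ = gen_ontology(20, n_genes=40, seed=15)
        ic = information_content(dag)
        max_ic = max(ic.values())
        terms = [t for t in dag.terms if t in ic]
        for t1, t2 in combinations(terms[:12], 2):
            common = dag.ancestors(t1) & dag.ancestors(t2)
            expected = max((ic[t] for t in common if t in ic), default=0.0) / max_ic
            assert math.isclose(resnik(dag, t1, t2, ic=ic), expected)

    def test_similarity_matrix_properties(self, toy_dag):
        sim = similarity_matrix(toy_dag, ["bcell", "neutro", "mitosis", "dual"])
        arr = sim.to_numpy()
        assert np.allclose(arr, arr.T)
        assert ((arr >= 0) & (arr <= 1)).all()
        assert (np.diag(arr) >= arr.max(axis=1) - 1e-12).all()


class TestORA:
    def test_hand_hypergeometric_case(self, toy_dag):
        """N=20, K=4, n=5, k=4: p equals the exact upper-tail sum."""
        universe = set(f"g{i}" for i in range(20))
        query = {"g0", "g1", "g2", "g3", "g15"}
        results = {r.term: r for r in ora(query, universe, toy_dag, p_max=1.0)}
        r = results["bcell"]  # leaf term: K=4 genes, all 4 hit
        expected = comb(4, 4, exact=True) * comb(16, 1, exact=True) / comb(20, 5, exact=True)
        assert math.isclose(r.p, expected, rel_tol=1e-12)
        assert (r.k, r.K, r.n, r.N) == (4, 4, 5, 20)

    def test_matches_enumeration_for_all_terms(self, toy_dag):
        """Every reported p equals brute-force enumeration over the toy DAG."""
        universe = set(f"g{i}" for i in range(20))
        rng = np.random.default_rng(3)
        query = set(rng.choice(sorted(universe), size=7, replace=False))
        for r in ora(query, universe, toy_dag, p_max=1.0):
            total = comb(20, 7, exact=True)
            hits = sum(
                comb(r.K, i, exact=True) * comb(20 - r.K, 7 - i, exact=True)
                for i in range(r.k, min(r.K, 7) + 1)
            )
            assert math.isclose(r.p, hits / total, rel_tol=1e-10)

    def test_pure_term_query_is_top_hit(self, toy_dag):
        universe = set(f"g{i}" for i in range(20))
        query = set(f"g{i}" for i in range(4))  # exactly bcell
        results = ora(query, universe, toy_dag, p_max=1.0)
        assert results[0].term == "bcell"

    def test_empty_query_and_bad_universe(self, toy_dag):
        universe = set(f"g{i}" for i in range(20))
        assert ora(set(), universe, toy_dag) == []
        with pytest.raises(ValueError):
            ora({"alien"}, universe, toy_dag)


class TestPruneRedundant:
    @staticmethod
    def _sim(labels, mat):
        return pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)

    def test_duplicate_terms_leave_one_survivor(self):
        sim = self._sim(["a", "b"], [[1, 1], [1, 1]])
        assert prune_redundant({"a": 0.01, "b": 0.02}, sim) == ["a"]

    def test_all_dissimilar_all_kept(self):
        sim = self._sim(["a", "b", "c"], np.eye(3))
        kept = prune_redundant({"a": 0.3, "b": 0.1, "c": 0.2}, sim)
        assert sorted(kept) == ["a", "b", "c"]

    def test_hand_traced_greedy_pass(self):
        labels = list("abcde")
        mat = np.eye(5)
        mat[0, 1] = mat[1, 0] = 0.9  # b collides with a
        mat[2, 3] = mat[3, 2] = 0.75  # d collides with c
        mat[0, 4] = mat[4, 0] = 0.6  # e survives (below 0.7)
        sim = self._sim(labels, mat)
        p = {"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04, "e": 0.05}
        assert prune_redundant(p, sim, threshold=0.7) == ["a", "c", "e"]

    def test_order_independent_given_tiebreak(self):
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(8)]
        base = rng.uniform(0, 1, size=(8, 8))
        sim = (base + base.T) / 2
        np.fill_diagonal(sim, 1.0)
        p = {t: 0.05 for t in labels}  # all tied -> term-id tiebreak
        df = self._sim(labels, sim)
        kept1 = prune_redundant(p, df, threshold=0.6)
        shuffled = {t: p[t] for t in reversed(labels)}
        kept2 = prune_redundant(shuffled, df, threshold=0.6)
        assert kept1 == kept2


class TestBinaryCut:
    @staticmethod
    def _sim(labels, mat):
        return pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)

    def test_two_perfect_blocks_recovered(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        mat = np.zeros((6, 6))
        mat[:3, :3] = 1.0
        mat[3:, 3:] = 1.0
        res = binary_cut(self._sim(labels, mat))
        got = {frozenset(c) for c in res.clusters}
        assert got == {frozenset(labels[:3]), frozenset(labels[3:])}

    def test_homogeneous_matrix_single_cluster(self):
        labels = [f"t{i}" for i in range(5)]
        res = binary_cut(self._sim(labels, np.full((5, 5), 0.9)))
        assert len(res.clusters) == 1

    def test_single_term_is_singleton(self):
        res = binary_cut(self._sim(["only"], [[1.0]]))
        assert res.clusters == [frozenset({"only"})]

    def test_planted_three_blocks_with_noise(self):
        """8 terms in 3 planted blocks, noise 0.05 -> ARI >= 0.9 vs truth."""
        rng = np.random.default_rng(19)
        truth = [0, 0, 0, 1, 1, 1, 2, 2]
        mat = np.full((8, 8), 0.1)
        for i in range(8):
            for j in range(8):
                if truth[i] == truth[j]:
                    mat[i, j] = 0.95
        noise = rng.normal(0, 0.05, size=(8, 8))
        mat = np.clip(mat + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(mat, 1.0)
        labels = [f"t{i}" for i in range(8)]
        res = binary_cut(self._sim(labels, mat))
        assign = res.labels()
        pred = [assign[t] for t in labels]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_partition_and_permutation_invariance(self):
        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(10)]
        base = rng.uniform(0.2, 1.0, size=(10, 10))
        sim = (base + base.T) / 2
        np.fill_diagonal(sim, 1.0)
        df = self._sim(labels, sim)
        res = binary_cut(df)
        members = [t for c in res.clusters for t in c]
        assert sorted(members) == sorted(labels)  # partition
        perm = rng.permutation(10)
        df2 = df.iloc[perm, perm]
        res2 = binary_cut(df2)
        assert {frozenset(c) for c in res.clusters} == {frozenset(c) for c in res2.clusters}

    def test_representative_is_smallest_p(self):
        labels = ["x", "y", "z"]
        res = binary_cut(
            self._sim(labels, np.full((3, 3), 0.95)),
            term_p={"x": 0.5, "y": 0.001, "z": 0.1},
        )
        assert res.representatives == ["y"]


class TestDisplayTables:
    def test_layout_tables(self, toy_dag):
        universe = set(f"g{i}" for i in range(20))
        query = set(f"g{i}" for i in range(8))
        lfc = {f"g{i}": (1.0 if i % 2 == 0 else -1.0) for i in range(20)}
        results = ora(query, universe, toy_dag, p_max=1.0, log2fc=lfc)
        sim = similarity_matrix(toy_dag, [r.term for r in results])
        clusters = binary_cut(sim, term_p={r.term: r.p for r in results},
                              term_size={r.term: r.K for r in results})
        tables = display_tables(results, clusters, lfc)
        words = tables["words"].set_index("gene")
        # g0 sits in root, immune and bcell (all enriched with k>=1 retained here)
        n_terms_with_g0 = sum(1 for r in results if "g0" in r.members)
        assert words.loc["g0", "frequency"] == n_terms_with_g0
        assert words.loc["g0", "sign"] == "up"
        treemap = tables["treemap"]
        for _, row in treemap.iterrows():
            assert row["cluster_area"] == len(clusters.clusters[row["cluster"]])
        ridge = tables["ridge"].set_index("term")
        for r in results:
            mean = np.mean([lfc[g] for g in r.members])
            assert math.isclose(ridge.loc[r.term, "mean_log2fc"], mean)
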