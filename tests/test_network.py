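import numpy as np
import pandas as pd
import pytest

from coralnet import (
    CorrelationNetwork,
    ValidationError,
    build_graph,
    centrality_group_tests,
    classification_accuracy,
    eigen_centrality,
    homophily,
    leading_eigenvector_communities,
    modularity,
    modularity_null,
    module_factor_chisq,
    sample_correlation,
)
from coralnet.network import ModulePartition, _stratified_shuffle


def set_partitions(n):
    """All partitions of range(n) via restricted-growth strings."""

    def rec(i, a, mx):
        if i == n:
            yield list(a)
            return
        for v in range(mx + 1):
            a.append(v)
            yield from rec(i + 1, a, max(mx, v + 1))
            a.pop()

    yield from rec(0, [], 0)


def exhaustive_max_modularity(w, max_n_full=8):
    """Brute-force modularity maximum: all set partitions for small n,
    all bipartitions otherwise."""
    n = w.shape[0]
    if n <= max_n_full:
        return max(modularity(w, np.array(p)) for p in set_partitions(n))
    best = modularity(w, np.zeros(n, dtype=int))
    for mask in range(1, 2 ** (n - 1)):
        member = np.array([(mask >> i) & 1 for i in range(n)])
        best = max(best, modularity(w, member))
    return best


def two_triangles():
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return w


def planted_blocks(n=10, inner=1.0, cross=0.05):
    w = np.full((n, n), cross)
    half = n // 2
    w[:half, :half] = inner
    w[half:, half:] = inner
    np.fill_diagonal(w, 0.0)
    return w


class TestSampleCorrelation:
    def test_hand_values(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1], [1, 2, 4]], index=list("abc"))
        r = sample_correlation(df)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert r.loc["a", "c"] == pytest.approx(0.982, abs=1e-3)

    def test_constant_sample_rejected(self):
        df = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            sample_correlation(df)


class TestHomophily:
    def test_constant_construction(self):
        n = 6
        labels = pd.Series(["A", "A", "A", "B", "B", "B"])
        r = np.full((n, n), 0.1)
        for block in ([0, 1, 2], [3, 4, 5]):
            r[np.ix_(block, block)] = 0.5
        np.fill_diagonal(r, 1.0)
        h = homophily(r, labels)
        assert h.homophily == pytest.approx(0.5)
        assert h.heterophily == pytest.approx(0.1)

    def test_single_level_flags_heterophily(self):
        r = np.full((3, 3), 0.4)
        with pytest.warns(UserWarning, match="heterophily"):
            h = homophily(r, pd.Series(["A", "A", "A"]), "genus")
        assert np.isnan(h.heterophily)

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(0)
        x = rng.random((8, 8))
        r = (x + x.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = np.array(["A", "B", "A", "B", "A", "B", "A", "B"])
        h1 = homophily(r, pd.Series(labels))
        renamed = pd.Series(np.where(labels == "A", "Porites", "Acropora"))
        h2 = homophily(r, renamed)
        perm = rng.permutation(8)
        h3 = homophily(r[np.ix_(perm, perm)], pd.Series(labels[perm]))
        assert h1.homophily == pytest.approx(h2.homophily) == pytest.approx(h3.homophily)
        assert h1.heterophily == pytest.approx(h2.heterophily) == pytest.approx(h3.heterophily)


class TestNegativePolicies:
    def test_policies(self):
        r = np.array([[1.0, 0.8, -0.3], [0.8, 1.0, 0.0], [-0.3, 0.0, 1.0]])
        trunc = build_graph(r, "truncate")
        assert trunc.w[0, 1] == pytest.approx(0.8)
        assert trunc.w[0, 2] == 0.0
        assert not trunc.graph.has_edge(0, 2)
        shift = build_graph(r, "shift")
        assert shift.w[0, 2] == pytest.approx(0.35)
        absolute = build_graph(r, "absolute")
        assert absolute.w[0, 2] == pytest.approx(0.3)

    def test_truncate_equals_absolute_when_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.random((5, 5))
        r = (x + x.T) / 2
        np.fill_diagonal(r, 1.0)
        np.testing.assert_allclose(build_graph(r, "truncate").w, build_graph(r, "absolute").w)


class TestModularity:
    def test_identities(self):
        w = two_triangles()
        assert modularity(w, np.zeros(6, dtype=int)) == pytest.approx(0.0, abs=1e-12)
        assert modularity(w, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)
        clique = np.ones((4, 4)) - np.eye(4)
        assert modularity(clique, np.arange(4)) < 0

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        x = rng.random((9, 9)) * (rng.random((9, 9)) > 0.4)
        w = np.triu(x, 1)
        w = w + w.T
        g = nx.from_numpy_array(w)
        member = rng.integers(0, 3, size=9)
        communities = [set(np.flatnonzero(member == k)) for k in range(3)]
        ref = nx.community.modularity(g, [c for c in communities if c], weight="weight")
        assert modularity(w, member) == pytest.approx(ref, abs=1e-12)


class TestLeadingEigenvector:
    def test_two_disconnected_triangles(self):
        part = leading_eigenvector_communities(two_triangles())
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-9)

    def test_complete_graph_single_module(self):
        w = np.ones((6, 6)) - np.eye(6)
        part = leading_eigenvector_communities(w)
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "w",
        [two_triangles(), planted_blocks(8), planted_blocks(10)],
        ids=["triangles", "blocks8", "blocks10"],
    )
    def test_matches_exhaustive_search(self, w):
        part = leading_eigenvector_communities(w)
        assert part.modularity == pytest.approx(exhaustive_max_modularity(w), abs=1e-9)

    def test_planted_blocks_recovered_and_matches_igraph(self):
        w = planted_blocks(10)
        part = leading_eigenvector_communities(w)
        member = part.assignment.to_numpy()
        assert len(set(member[:5])) == 1 and len(set(member[5:])) == 1
        assert member[0] != member[5]
        import igraph as ig

        g = ig.Graph.Weighted_Adjacency(w.tolist(), mode="undirected")
        ref = g.community_leading_eigenvector(weights="weight")
        assert part.modularity == pytest.approx(ref.modularity, abs=1e-9)

    def test_module_ids_canonical_by_size(self):
        # 4-clique plus 3-clique, weakly joined: module 0 is the larger one
        w = np.zeros((7, 7))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        w[0, 4] = w[4, 0] = 0.01
        part = leading_eigenvector_communities(w)
        assert (part.assignment.to_numpy()[:4] == 0).all()


class TestModularityNull:
    def test_shuffle_preserves_stratum_multisets(self):
        rng = np.random.default_rng(0)
        x = rng.random((8, 8))
        r = (x + x.T) / 2
        np.fill_diagonal(r, 1.0)
        strata = np.array(["A"] * 4 + ["B"] * 4)
        M = _stratified_shuffle(r.copy(), strata, np.random.default_rng(1))
        off = ~np.eye(8, dtype=bool)
        # multiset of each stratum's row values is preserved before averaging;
        # check on the raw permuted matrix by regenerating with same rng
        M_raw = r.copy()
        rng2 = np.random.default_rng(1)
        for lev in np.unique(strata):
            rows = np.flatnonzero(strata == lev)
            mask = np.zeros_like(off)
            mask[rows] = off[rows]
            M_raw[mask] = rng2.permutation(M_raw[mask])
            np.testing.assert_allclose(
                np.sort(M_raw[mask]), np.sort(r[mask]), atol=1e-15
            )
        np.testing.assert_allclose(M, (M_raw + M_raw.T) / 2, atol=1e-15)

    def test_planted_structure_significant(self):
        rng = np.random.default_rng(5)
        r = planted_blocks(12, inner=0.9, cross=0.05)
        r += rng.normal(0, 0.01, size=r.shape)
        r = np.clip((r + r.T) / 2, -1, 1)
        np.fill_diagonal(r, 1.0)
        net = CorrelationNetwork(list(range(12)), r)
        labels = pd.Series(["A"] * 6 + ["B"] * 6)
        p, q_obs, nulls = modularity_null(net, labels, permutations=99, seed=3)
        assert p == 0.0  # no null modularity reaches the planted one
        assert q_obs > nulls.max()

    def test_requires_permutations(self):
        net = CorrelationNetwork(list(range(4)), np.eye(4))
        with pytest.raises(ValueError):
            modularity_null(net, pd.Series(["A"] * 4), permutations=0)


class TestModuleFactorAssociation:
    def test_chisq_hand_example(self):
        part = ModulePartition(pd.Series([0] * 10 + [1] * 10), 0.3)
        labels = pd.Series(["A"] * 10 + ["B"] * 10)
        tt = module_factor_chisq(part, labels, "genus")
        row = tt.frame.iloc[0]
        assert row["statistic"] == pytest.approx(20.0)
        assert row["df"] == 1

    def test_six_by_six_df(self):
        rng = np.random.default_rng(0)
        assign = pd.Series(np.repeat(np.arange(6), 12))
        labels = pd.Series(rng.permutation(np.repeat([f"sp{k}" for k in range(6)], 12)))
        tt = module_factor_chisq(ModulePartition(assign, 0.1), labels, "species")
        assert tt.frame.iloc[0]["df"] == 25

    def test_classification_accuracy_majority_count(self):
        assign = pd.Series([0] * 20 + [1] * 10)
        labels = pd.Series(["A"] * 19 + ["B"] * 11)
        acc = classification_accuracy(ModulePartition(assign, 0.2), labels, ["A", "B"])
        assert acc == pytest.approx(29 / 30)

    def test_pure_modules_fully_correct(self):
        assign = pd.Series([0, 0, 1, 1])
        labels = pd.Series(["A", "A", "B", "B"])
        assert classification_accuracy(ModulePartition(assign, 0.5), labels) == 1.0


class TestEigenCentrality:
    def test_complete_graph_all_ones(self):
        w = np.ones((5, 5)) - np.eye(5)
        c = eigen_centrality(w)
        np.testing.assert_allclose(c, 1.0, atol=1e-8)

    def test_star_closed_form(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        c = eigen_centrality(w)
        assert c.iloc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(c.iloc[1:], 1 / np.sqrt(3), atol=1e-8)

    def test_eigenvector_residual(self):
        rng = np.random.default_rng(1)
        x = rng.random((10, 10))
        w = (x + x.T) / 2
        np.fill_diagonal(w, 0.0)
        c = eigen_centrality(w).to_numpy()
        lam = c @ w @ c / (c @ c)
        resid = np.linalg.norm(w @ c - lam * c) / np.linalg.norm(c)
        assert resid < 1e-8

    def test_disconnected_nodes_score_zero(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = w[2, 4] = w[4, 2] = w[3, 4] = w[4, 3] = 1.0
        c = eigen_centrality(w)
        # triangle is the largest component; the pair scores 0
        assert c.iloc[2] == pytest.approx(1.0)
        assert c.iloc[0] == 0.0

    def test_group_tests_holm_adjusted(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(np.concatenate([rng.normal(0.9, 0.02, 10),
                                           rng.normal(0.5, 0.02, 10),
                                           rng.normal(0.2, 0.02, 10)]))
        labels = pd.Series(["P"] * 10 + ["A"] * 10 + ["D"] * 10)
        res = centrality_group_tests(scores, labels, "genus", ["P", "A", "D"])
        assert list(res.group_stats["level"]) == ["P", "A", "D"]
        assert (res.pairwise.frame["p_adjusted"] >= res.pairwise.frame["p_value"] - 1e-18).all()
        assert (res.pairwise.frame["p_adjusted"] < 0.05).all()
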