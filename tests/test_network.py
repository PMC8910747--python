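import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netsubtype.network import (
    build_network,
    centralities,
    delta_betweenness,
    detect_communities,
    pcit_mask,
    pearson_matrix,
)
from tests.conftest import expr_from_array


def pcit_oracle(R):
    """Brute-force O(n^3) trio enumeration, independent of the vectorized
    implementation."""
    n = R.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)

    def partial(a, b, c):
        num = R[a, b] - R[a, c] * R[b, c]
        den = np.sqrt(max((1 - R[a, c] ** 2) * (1 - R[b, c] ** 2), 1e-12))
        return num / den

    def ratio(a, b, c):
        if R[a, b] == 0:
            return 0.0
        return abs(partial(a, b, c)) / abs(R[a, b])

    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z in (x, y):
                    continue
                eps = (ratio(x, y, z) + ratio(x, z, y) + ratio(y, z, x)) / 3.0
                if abs(R[x, y]) < eps * abs(R[x, z]) and abs(R[x, y]) < eps * abs(R[y, z]):
                    eliminated[x, y] = True
    mask = ~(eliminated | eliminated.T)
    np.fill_diagonal(mask, False)
    return mask


def random_corr(rng, n):
    """A valid correlation matrix from random data."""
    X = rng.normal(size=(n, n + 10))
    return np.corrcoef(X)


class TestPearson:
    def test_duplicated_gene_r_one(self, rng):
        x = rng.normal(size=30)
        E = expr_from_array(np.vstack([x, x, rng.normal(size=30)]))
        R = pearson_matrix(E)
        assert R[0, 1] == pytest.approx(1.0)

    def test_textbook_formula_oracle(self, rng):
        X = rng.normal(size=(5, 6))
        E = expr_from_array(X)
        R = pearson_matrix(E)
        for i in range(5):
            for j in range(5):
                xi, xj = X[i], X[j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                assert R[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_independent_genes_small_r(self):
        rng = np.random.default_rng(1)
        E = expr_from_array(rng.normal(size=(10, 1000)))
        R = pearson_matrix(E)
        off = R[np.triu_indices(10, 1)]
        assert np.median(np.abs(off)) < 0.1

    def test_zero_variance_gene(self, rng):
        X = rng.normal(size=(3, 10))
        X[1] = 5.0
        R = pearson_matrix(expr_from_array(X))
        assert (R[1, [0, 2]] == 0).all()
        assert R[1, 1] == 1.0

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            pearson_matrix(expr_from_array(rng.normal(size=(5, 3))))
        with pytest.raises(ValueError):
            pearson_matrix(expr_from_array(rng.normal(size=(2, 10))))


class TestPcit:
    def test_identity_no_edges(self):
        mask, weights = pcit_mask(np.eye(6))
        assert not mask.any()
        assert (weights == 0).all()

    def test_partial_correlation_closed_form(self):
        # r_xy=0.8, r_xz=0.5, r_yz=0.5 -> r_xy.z = 0.55/0.75
        num = 0.8 - 0.5 * 0.5
        den = np.sqrt((1 - 0.25) * (1 - 0.25))
        assert num / den == pytest.approx(0.73333, abs=1e-4)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(8, 13))
            R = random_corr(rng, n)
            mask, weights = pcit_mask(R)
            assert (mask == pcit_oracle(R)).all(), f"trial {trial}"
            assert np.allclose(weights, np.where(mask, R, 0.0))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        R = random_corr(rng, 10)
        perm = rng.permutation(10)
        mask1, _ = pcit_mask(R)
        mask2, _ = pcit_mask(R[np.ix_(perm, perm)])
        assert (mask2 == mask1[np.ix_(perm, perm)]).all()

    def test_invalid_r_rejected(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 1.5
        with pytest.raises(ValueError):
            pcit_mask(R)


class TestBuildNetwork:
    def test_self_loop_removed(self):
        mask = np.eye(3, dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        net = build_network(["a", "b", "c"], mask, np.ones((3, 3)))
        assert net.n_edges == 1
        assert "c" not in net.nodes  # isolated node pruned

    def test_isolated_pruned_and_conserved(self):
        # star a-b, a-c, a-d plus isolated e
        nodes = list("abcde")
        mask = np.zeros((5, 5), dtype=bool)
        for j in (1, 2, 3):
            mask[0, j] = mask[j, 0] = True
        net = build_network(nodes, mask, np.ones((5, 5)) * 0.5)
        assert net.n_nodes == 4
        assert net.n_nodes + len(net.pruned_nodes) == 5

    def test_empty_allowed(self):
        net = build_network(["a", "b"], np.zeros((2, 2), bool), np.zeros((2, 2)))
        assert net.n_nodes == 0

    def test_edgelist_roundtrip(self, tmp_path):
        mask = np.array([[False, True], [True, False]])
        net = build_network(["a", "b"], mask, np.full((2, 2), 0.7), group="g1")
        path = tmp_path / "edges.tsv"
        net.write_edgelist(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert df.iloc[0].tolist() == ["a", "b", 0.7, "g1"]


def _clique_network(sizes, p_out=0.0, rng=None):
    n = sum(sizes)
    mask = np.zeros((n, n), dtype=bool)
    start = 0
    for size in sizes:
        idx = np.arange(start, start + size)
        for i in idx:
            for j in idx:
                if i != j:
                    mask[i, j] = True
        start += size
    if rng is not None and p_out > 0:
        blocks = np.repeat(np.arange(len(sizes)), sizes)
        for i in range(n):
            for j in range(i + 1, n):
                if blocks[i] != blocks[j] and rng.uniform() < p_out:
                    mask[i, j] = mask[j, i] = True
    weights = mask.astype(float)
    return build_network([f"n{i}" for i in range(n)], mask, weights)


class TestCommunities:
    def test_two_disconnected_cliques(self):
        net = _clique_network([4, 4])
        ca = detect_communities(net, seed=1)
        assert ca.n_communities == 2
        assert ca.converged

    def test_single_clique(self):
        net = _clique_network([6])
        assert detect_communities(net, seed=2).n_communities == 1

    def test_planted_partition_recovery(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 30
            blocks = np.repeat([0, 1], 15)
            mask = np.zeros((n, n), dtype=bool)
            for i in range(n):
                for j in range(i + 1, n):
                    p = 0.9 if blocks[i] == blocks[j] else 0.05
                    if rng.uniform() < p:
                        mask[i, j] = mask[j, i] = True
            net = build_network([f"n{i}" for i in range(n)], mask, mask.astype(float))
            ca = detect_communities(net, seed=seed)
            found = [ca.communities[f"n{i}"] for i in range(n) if f"n{i}" in ca.communities]
            keep = [i for i in range(n) if f"n{i}" in ca.communities]
            if adjusted_rand_score(blocks[keep], found) >= 0.9:
                wins += 1
        assert wins >= 18

    def test_empty_rejected(self):
        net = build_network(["a"], np.zeros((1, 1), bool), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            detect_communities(net)


class TestCentralities:
    def _path3(self):
        mask = np.array([
            [False, True, False],
            [True, False, True],
            [False, True, False],
        ])
        return build_network(["A", "B", "C"], mask, mask.astype(float))

    def test_path_betweenness_hand_values(self):
        ct = centralities(self._path3(), weighted=False)
        assert np.allclose(ct.table["betweenness"], [0, 1, 0])
        assert np.allclose(ct.table["betweenness_z"], [-0.57735, 1.154701, -0.57735],
                           atol=1e-5)

    def test_path_authority_eigenvector(self):
        ct = centralities(self._path3())
        assert np.allclose(ct.table["authority"], [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
                           atol=1e-8)

    def test_star_leaves_equal(self):
        mask = np.zeros((5, 5), dtype=bool)
        for j in range(1, 5):
            mask[0, j] = mask[j, 0] = True
        net = build_network([f"n{i}" for i in range(5)], mask, mask * 0.3)
        ct = centralities(net)
        leaves = ct.table["authority"].to_numpy()[1:]
        assert np.allclose(leaves, leaves[0])

    def test_authority_matches_dense_eig(self, rng):
        n = 20
        W = np.abs(rng.normal(size=(n, n)))
        W = (W + W.T) / 2
        mask = rng.uniform(size=(n, n)) < 0.3
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        net = build_network([f"n{i}" for i in range(n)], mask, np.where(mask, W, 0))
        if net.n_edges == 0:
            pytest.skip("degenerate draw")
        ct = centralities(net)
        A = np.abs(net.weights)
        vals, vecs = np.linalg.eigh(A)
        lead = np.abs(vecs[:, np.argmax(vals)])
        lead /= lead.max()
        assert np.allclose(ct.table["authority"], lead, atol=1e-8)

    def test_zero_network_error(self):
        net = build_network(["a"], np.zeros((1, 1), bool), np.zeros((1, 1)),
                            prune_isolated=False)
        with pytest.raises(ValueError):
            centralities(net)


class TestDeltaBetweenness:
    def _net(self, edges, nodes):
        n = len(nodes)
        index = {g: i for i, g in enumerate(nodes)}
        mask = np.zeros((n, n), dtype=bool)
        for a, b in edges:
            mask[index[a], index[b]] = mask[index[b], index[a]] = True
        return build_network(nodes, mask, mask.astype(float), prune_isolated=False)

    def test_identical_networks_zero(self):
        net = self._net([("a", "b"), ("b", "c")], ["a", "b", "c"])
        delta = delta_betweenness(net, net)
        assert np.allclose(delta.to_numpy(), 0.0)

    def test_antisymmetry(self):
        n1 = self._net([("a", "b"), ("b", "c"), ("c", "d")], list("abcd"))
        n2 = self._net([("a", "b"), ("a", "c"), ("a", "d")], list("abcd"))
        d12 = delta_betweenness(n1, n2).sort_index()
        d21 = delta_betweenness(n2, n1).sort_index()
        assert np.allclose(d12.to_numpy(), -d21.to_numpy())

    def test_hub_only_in_net1_max_delta(self):
        # b is a hub (path center) in net1 but absent from net2
        n1 = self._net([("a", "b"), ("b", "c"), ("c", "d")], list("abcd"))
        n2 = self._net([("a", "c"), ("c", "d")], list("acd"))
        delta = delta_betweenness(n1, n2)
        assert delta.abs().idxmax() == "b"
        assert delta.index[0] == "b"  # sorted by |delta| descending
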