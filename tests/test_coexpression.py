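import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import drugsig as ds


def brute_force_mst_weight(D):
    """Minimum total weight over all spanning trees (exhaustive, n <= 7)."""
    n = D.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(edges, n - 1):
        G = nx.Graph(combo)
        if G.number_of_nodes() == n and nx.is_connected(G):
            w = sum(D[i, j] for i, j in combo)
            best = min(best, w)
    return best


def random_distance_frame(rng, n, ids=None):
    M = rng.uniform(0.1, 2.0, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = ids or [f"t{i}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)


class TestSpearmanDistance:
    def test_monotone_transform_gives_zero_distance(self):
        prof = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], np.exp([1.0, 2.0, 3.0, 4.0])], index=["u", "v"]
        )
        d = ds.spearman_distance(prof)
        assert d.loc["u", "v"] == pytest.approx(0.0)

    def test_reversed_ranks_give_distance_two(self):
        prof = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["u", "v"], dtype=float)
        assert ds.spearman_distance(prof).loc["u", "v"] == pytest.approx(2.0)

    def test_hand_computed_rank_correlation(self):
        prof = pd.DataFrame([[1, 2, 3, 4], [1, 3, 2, 4]], index=["u", "v"], dtype=float)
        assert ds.spearman_distance(prof).loc["u", "v"] == pytest.approx(0.2)

    def test_constant_profile_gets_sentinel_distance(self):
        prof = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2, 1, 4, 3]],
            index=["u", "c", "v"],
        )
        with pytest.warns(UserWarning, match="constant"):
            d = ds.spearman_distance(prof)
        assert d.loc["c", "u"] == 1.0
        assert d.loc["c", "v"] == 1.0

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(10, 8)))
        d = ds.spearman_distance(prof)
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert (np.diag(d.to_numpy()) == 0).all()


class TestBuildMST:
    def test_three_node_hand_example(self):
        D = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        T = ds.build_mst(D)
        assert set(map(frozenset, T.edges())) == {frozenset("ab"), frozenset("bc")}
        assert sum(d["weight"] for _, _, d in T.edges(data=True)) == 3.0

    def test_matches_exhaustive_minimum_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            D = random_distance_frame(rng, n)
            T = ds.build_mst(D)
            w = sum(d["weight"] for _, _, d in T.edges(data=True))
            assert w == pytest.approx(brute_force_mst_weight(D.to_numpy()))

    def test_tree_properties(self):
        rng = np.random.default_rng(2)
        D = random_distance_frame(rng, 30)
        T = ds.build_mst(D)
        assert T.number_of_edges() == 29
        assert nx.is_connected(T)

    def test_deterministic_under_ties(self):
        # all distances equal: lexicographic tie-break fixes the tree
        ids = ["b", "a", "d", "c"]
        D = pd.DataFrame(1.0, index=ids, columns=ids)
        np.fill_diagonal(D.to_numpy(), 0.0)
        T = ds.build_mst(D)
        assert set(map(tuple, map(sorted, T.edges()))) == {
            ("a", "b"), ("a", "c"), ("a", "d"),
        }

    def test_nan_rejected(self):
        D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="NaN"):
            ds.build_mst(D)


class TestWalkLength:
    def test_adjacent_and_path_endpoints(self):
        T = nx.path_graph(6)
        assert ds.walk_length(T, [(0, 1)]) == [1]
        assert ds.walk_length(T, [(0, 5)]) == [5]

    def test_equals_bfs_on_random_trees(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            T = nx.random_labeled_tree(20, seed=int(rng.integers(1 << 30)))
            pairs = [
                (int(rng.integers(20)), int(rng.integers(20))) for _ in range(15)
            ]
            got = ds.walk_length(T, pairs)
            exp = [nx.shortest_path_length(T, u, v) for u, v in pairs]
            assert got == exp

    def test_unknown_node_rejected(self):
        T = nx.path_graph(3)
        with pytest.raises(KeyError, match="99"):
            ds.walk_length(T, [(0, 99)])


class TestExtractNetworks:
    def test_close_chain_is_one_network(self):
        T = nx.path_graph(20)
        selected = [0, 3, 6, 9, 12]
        nets = ds.extract_networks(T, selected, cutoff=4, min_network_size=2)
        assert len(nets.networks) == 1
        assert sorted(nets.networks["net_1"]) == selected

    def test_five_edge_gap_splits_networks(self):
        T = nx.path_graph(20)
        selected = [0, 2, 4, 9, 11, 13]
        nets = ds.extract_networks(T, selected, cutoff=4, min_network_size=2)
        assert len(nets.networks) == 2

    def test_small_clusters_unassigned(self):
        T = nx.path_graph(30)
        selected = [0, 2, 4, 6, 20]
        nets = ds.extract_networks(T, selected, cutoff=4, min_network_size=3)
        assert nets.labels[20] == "unassigned"

    def test_matches_single_linkage_cut(self):
        # single-linkage dendrogram cut == components of thresholded graph
        rng = np.random.default_rng(4)
        for seed in range(20):
            T = nx.random_labeled_tree(30, seed=int(rng.integers(1 << 30)))
            selected = sorted(rng.choice(30, size=12, replace=False).tolist())
            nets = ds.extract_networks(T, selected, cutoff=3, min_network_size=1)
            D = np.array(
                [
                    [nx.shortest_path_length(T, u, v) for v in selected]
                    for u in selected
                ],
                dtype=float,
            )
            Z = hierarchy.linkage(squareform(D), method="single")
            cut = hierarchy.fcluster(Z, t=3, criterion="distance")
            ours = pd.Series(nets.labels.loc[selected].to_numpy())
            theirs = pd.Series(cut)
            # identical partitions up to label names
            assert (
                ours.groupby(theirs.to_numpy()).nunique().max() == 1
                and theirs.groupby(ours.to_numpy()).nunique().max() == 1
            )

    def test_invariant_to_input_order(self):
        T = nx.path_graph(15)
        sel = [0, 2, 4, 10, 12]
        a = ds.extract_networks(T, sel, cutoff=4, min_network_size=2)
        b = ds.extract_networks(T, sel[::-1], cutoff=4, min_network_size=2)
        assert a.networks == b.networks

    def test_smaller_cutoff_never_merges(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            T = nx.random_labeled_tree(40, seed=int(rng.integers(1 << 30)))
            selected = sorted(rng.choice(40, size=15, replace=False).tolist())
            coarse = ds.extract_networks(T, selected, cutoff=5, min_network_size=1)
            fine = ds.extract_networks(T, selected, cutoff=2, min_network_size=1)
            # refinement: every fine cluster sits inside one coarse cluster
            fine_lab = fine.labels
            coarse_lab = coarse.labels
            for _, members in fine.networks.items():
                assert coarse_lab.loc[members].nunique() == 1

    def test_cutoff_below_one_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            ds.extract_networks(nx.path_graph(3), [0, 1], cutoff=0)

    def test_planted_modules_recovered(self, study_run):
        from sklearn.metrics import adjusted_rand_score

        fct, truth = study_run["fct"], study_run["truth"]
        scores = study_run["scores"]
        sel = ds.select_transcripts(scores, "top_k", 75)
        dist = ds.spearman_distance(ds.expression_profiles(fct))
        tree = ds.build_mst(dist)
        nets = ds.extract_networks(tree, sel, cutoff=4, min_network_size=8)
        memb = truth.network_membership.loc[nets.labels.index]
        assert adjusted_rand_score(memb, nets.labels) >= 0.9


def test_tree_writers(tmp_path, study_run):
    fct = study_run["fct"]
    dist = ds.spearman_distance(
        ds.expression_profiles(fct).iloc[:20]
    )
    tree = ds.build_mst(dist)
    from drugsig.coexpression import write_tree

    write_tree(tree, tmp_path / "edges.tsv", tmp_path / "t.graphml")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert len(edges) == 19
    back = nx.read_graphml(tmp_path / "t.graphml")
    assert back.number_of_nodes() == 20
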