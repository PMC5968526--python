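import numpy as np
import networkx as nx
import pytest

from flockgen.networks import (
    SplitSystem,
    _circular_splits,
    neighbor_joining,
    neighbor_net,
    parse_newick,
    read_nexus_splits,
    terminal_branch_lengths,
    tree_distance_matrix,
    tree_splits,
    write_newick,
    write_nexus_splits,
)
from flockgen.structure import DistanceMatrix


def random_additive_tree(rng, n):
    """Random binary tree with uniform branch lengths; leaves T0..T{n-1}."""
    ids = [f"T{i}" for i in range(n)]
    tree = nx.Graph()
    for leaf in ids[:3]:
        tree.add_edge(leaf, "#r", length=rng.uniform(0.1, 1.0))
    k = 0
    for leaf in ids[3:]:
        a, b = list(tree.edges)[rng.integers(len(tree.edges))]
        L = tree.edges[a, b]["length"]
        f = rng.uniform(0.2, 0.8)
        mid = f"#m{k}"
        k += 1
        tree.remove_edge(a, b)
        tree.add_edge(a, mid, length=L * f)
        tree.add_edge(b, mid, length=L * (1 - f))
        tree.add_edge(leaf, mid, length=rng.uniform(0.1, 1.0))
    return tree


def canonical(split_weights, taxa):
    ref = min(taxa)
    out = {}
    for s, w in split_weights.items():
        if ref in s:
            s = frozenset(taxa) - s
        out[s] = out.get(s, 0.0) + w
    return out


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = neighbor_joining(dm)
        assert tree.edges["A", "B"]["length"] == pytest.approx(0.4)

    def test_three_point_formulas(self):
        dm = DistanceMatrix(["1", "2", "3"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        lengths = terminal_branch_lengths(neighbor_joining(dm))
        assert lengths == pytest.approx({"1": 0.5, "2": 1.5, "3": 2.5})

    def test_consistency_on_additive_metrics(self, rng):
        for _ in range(100):
            tree = random_additive_tree(rng, 8)
            dm = tree_distance_matrix(tree)
            nj = neighbor_joining(dm)
            a = canonical(tree_splits(tree), dm.ids)
            b = canonical(tree_splits(nj), dm.ids)
            assert set(a) == set(b)
            for s in a:
                assert a[s] == pytest.approx(b[s], abs=1e-9)

    def test_relabeling_equivariance(self, rng):
        tree = random_additive_tree(rng, 6)
        dm = tree_distance_matrix(tree)
        nj1 = neighbor_joining(dm)
        mapping = {t: f"Z{t}" for t in dm.ids}
        dm2 = DistanceMatrix([mapping[t] for t in dm.ids], dm.values)
        nj2 = neighbor_joining(dm2)
        d1 = tree_distance_matrix(nj1)
        d2 = tree_distance_matrix(nj2)
        perm = [d2.ids.index(mapping[t]) for t in d1.ids]
        assert np.allclose(d1.values, d2.values[np.ix_(perm, perm)], atol=1e-12)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A"], np.zeros((1, 1))))


class TestNewick:
    def test_two_leaf_format(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert write_newick(neighbor_joining(dm)) == "(A:0.2,B:0.2);"

    def test_roundtrip(self, rng):
        tree = random_additive_tree(rng, 7)
        back = parse_newick(write_newick(tree))
        d1, d2 = tree_distance_matrix(tree), tree_distance_matrix(back)
        assert d1.ids == d2.ids
        assert np.allclose(d1.values, d2.values, atol=1e-9)

    def test_reserved_characters_quoted(self):
        dm = DistanceMatrix(["A B", "C:D"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        text = write_newick(neighbor_joining(dm))
        assert "'A B'" in text and "'C:D'" in text

    def test_byte_stable(self, rng):
        tree = random_additive_tree(rng, 6)
        assert write_newick(tree) == write_newick(tree.copy())


class TestNeighborNet:
    def test_tree_metric_recovers_tree_splits(self, rng):
        for _ in range(10):
            tree = random_additive_tree(rng, 8)
            dm = tree_distance_matrix(tree)
            net = neighbor_net(dm)
            a = canonical(tree_splits(tree), dm.ids)
            b = net.canonical_splits()
            assert set(a) == set(b)
            for s in a:
                assert a[s] == pytest.approx(b[s], abs=1e-6)

    def test_planted_circular_metric_recovered(self, rng):
        for _ in range(10):
            ids = [f"T{i}" for i in range(9)]
            order = list(rng.permutation(ids))
            splits = _circular_splits(order)
            pick = rng.choice(len(splits), size=15, replace=False)
            planted = SplitSystem(ids, order,
                                  [splits[i] for i in pick],
                                  list(rng.uniform(0.2, 1.0, size=15)))
            dm = planted.induced_distance_matrix()
            net = neighbor_net(dm)
            got = net.induced_distance_matrix()
            perm = [got.ids.index(t) for t in dm.ids]
            assert np.allclose(got.values[np.ix_(perm, perm)], dm.values, atol=1e-6)
            a, b = planted.canonical_splits(), net.canonical_splits()
            assert set(a) == set(b)
            for s in a:
                assert a[s] == pytest.approx(b[s], abs=1e-6)

    def test_all_zero_distances_empty_splits(self):
        dm = DistanceMatrix(list("ABCDE"), np.zeros((5, 5)))
        assert neighbor_net(dm).splits == []

    def test_negative_entries_clamped_with_warning(self):
        vals = np.array([[0, -0.01, 0.3], [-0.01, 0, 0.3], [0.3, 0.3, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            net = neighbor_net(DistanceMatrix(list("ABC"), vals))
        assert all(w >= 0 for w in net.weights)

    def test_small_n_trivial_system(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        net = neighbor_net(dm)
        assert net.induced_distance_matrix().values[0, 1] == pytest.approx(0.8)


class TestNexus:
    def test_roundtrip(self, rng):
        ids = [f"T{i}" for i in range(6)]
        order = list(rng.permutation(ids))
        splits = _circular_splits(order)
        pick = rng.choice(len(splits), size=8, replace=False)
        system = SplitSystem(ids, order, [splits[i] for i in pick],
                             list(rng.uniform(0.1, 1.0, size=8)))
        back = read_nexus_splits(write_nexus_splits(system))
        assert back.taxa == system.taxa
        assert back.circular_order == system.circular_order
        assert back.canonical_splits().keys() == system.canonical_splits().keys()
        for s, w in system.canonical_splits().items():
            assert back.canonical_splits()[s] == pytest.approx(w, abs=1e-9)

    def test_contains_required_blocks(self):
        system = SplitSystem(["A", "B"], ["A", "B"], [frozenset(["B"])], [0.5])
        text = write_nexus_splits(system)
        assert "BEGIN TAXA;" in text and "BEGIN SPLITS;" in text and "CYCLE" in text
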