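import numpy as np
import pytest

from oracles import naive_agglomerate, random_connectivity
from vigilnet.connectivity import ConnectivityMatrix
from vigilnet.netcluster import (ClassAssignment, ConnectionClusterClassifier,
                                 agglomerate, agglomerate_distances,
                                 assign_classes, class_trajectory,
                                 connection_cluster_distances, cut,
                                 louvain_communities, modularity_brute,
                                 node_vectors)

# Five collinear one-attribute nodes realising the canonical exemplar
# dendrogram: C1+C2 -> C6, C6+C3 -> C7, C7+C4 -> C8, C8+C5 -> C9.
EXEMPLAR_POSITIONS = np.array([[0.0], [0.5], [1.5], [3.5], [7.5]])


class TestNodeVectors:
    def test_three_node_read_off(self):
        a, b, c = 0.2, 0.5, 0.8
        F = np.array([[0, a, b], [a, 0, c], [b, c, 0]], dtype=float)
        X = node_vectors(F)
        np.testing.assert_array_equal(X, [[a, b], [a, c], [b, c]])

    def test_matches_row_extraction(self, rng):
        F = random_connectivity(rng, 6)
        X = node_vectors(F)
        assert X.shape == (6, 5)
        for i in range(6):
            np.testing.assert_array_equal(X[i], np.delete(F[i], i))

    def test_permutation_equivariance(self, rng):
        F = random_connectivity(rng, 5)
        perm = rng.permutation(5)
        Xp = node_vectors(F[np.ix_(perm, perm)])
        for row, orig in enumerate(perm):
            assert set(np.round(Xp[row], 12)) == set(
                np.round(node_vectors(F)[orig], 12))


class TestAgglomerate:
    def test_two_nodes_single_merge(self):
        d = agglomerate(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert len(d.merges) == 1
        m = d.merges[0]
        assert (m.left, m.right, m.new) == (1, 2, 3)
        assert m.distance == pytest.approx(5.0)

    def test_nearest_pair_merges_first(self):
        d = agglomerate(np.array([[0.0], [1.0], [10.0]]))
        assert (d.merges[0].left, d.merges[0].right) == (1, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            agglomerate(np.empty((0, 2)))

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_naive_reclustering(self, rng, linkage):
        """100 seeded 6-node instances against O(N^3) recomputation."""
        for _ in range(100):
            X = node_vectors(random_connectivity(rng, 6))
            ours = [(m.step, m.left, m.right, m.new) for m in
                    agglomerate(X, linkage).merges]
            theirs = [(s, a, b, new) for s, a, b, new, _ in
                      naive_agglomerate(X, linkage)]
            assert ours == theirs
            for m, (_, _, _, _, d) in zip(agglomerate(X, linkage).merges,
                                          naive_agglomerate(X, linkage)):
                assert m.distance == pytest.approx(d, abs=1e-12)

    def test_single_linkage_distances_nondecreasing(self, rng):
        for _ in range(20):
            X = node_vectors(random_connectivity(rng, 7))
            d = [m.distance for m in agglomerate(X, "single").merges]
            assert all(a <= b + 1e-12 for a, b in zip(d, d[1:]))

    def test_scale_covariance(self, rng):
        X = node_vectors(random_connectivity(rng, 6))
        base = agglomerate(X)
        scaled = agglomerate(2.5 * X)
        for m, ms in zip(base.merges, scaled.merges):
            assert (m.left, m.right, m.new) == (ms.left, ms.right, ms.new)
            assert ms.distance == pytest.approx(2.5 * m.distance, rel=1e-10)


class TestCutAndClasses:
    def test_cut_extremes(self, rng):
        X = node_vectors(random_connectivity(rng, 5))
        d = agglomerate(X)
        whole = cut(d, 1)
        assert list(whole.values()) == [(1, 2, 3, 4, 5)]
        singles = cut(d, 5)
        assert sorted(singles.values()) == [(i,) for i in range(1, 6)]

    def test_cut_out_of_range(self, rng):
        d = agglomerate(node_vectors(random_connectivity(rng, 4)))
        for z in (0, 5):
            with pytest.raises(ValueError):
                cut(d, z)

    def test_exemplar_four_way_cut(self):
        d = agglomerate(EXEMPLAR_POSITIONS)
        merged = [(m.left, m.right, m.new) for m in d.merges]
        assert merged == [(1, 2, 6), (3, 6, 7), (4, 7, 8), (5, 8, 9)]
        part = cut(d, 4)
        assert part == {3: (3,), 4: (4,), 5: (5,), 6: (1, 2)}

    def test_exemplar_merge_order_classes(self):
        """The cluster absorbed last gets the highest class: C6 -> 1,
        C3 -> 2, C4 -> 3, C5 -> 4."""
        d = agglomerate(EXEMPLAR_POSITIONS)
        assignment = assign_classes(d, 4)
        assert assignment.labels == {1: 1, 2: 1, 3: 2, 4: 3, 5: 4}

    def test_hand_traced_instance(self):
        # positions 0, 1, 5, 12, 30: merges (1,2)@1, (3,C6)@4, (4,C7)@7,
        # (5,C8)@18; Z=3 cut -> {C7}, {4}, {5}; absorption: C7&4 tie at the
        # next step (min node rule: C7 first), then 5.
        d = agglomerate(np.array([[0.0], [1.0], [5.0], [12.0], [30.0]]))
        assignment = assign_classes(d, 3)
        assert assignment.labels == {1: 1, 2: 1, 3: 1, 4: 2, 5: 3}

    def test_single_class_when_z_is_one(self, rng):
        d = agglomerate(node_vectors(random_connectivity(rng, 5)))
        assert set(assign_classes(d, 1).labels.values()) == {1}

    def test_all_classes_used_exactly_once(self, rng):
        for _ in range(20):
            F = random_connectivity(rng, 8)
            d = agglomerate(node_vectors(F))
            labels = assign_classes(d, 4)
            part = cut(d, 4)
            classes = sorted({labels.labels[min(p)] for p in part.values()})
            assert classes == [1, 2, 3, 4]

    def test_permutation_equivariance_of_classes(self, rng):
        """Relabeling nodes permutes the class partition identically.

        Class ranks are stable under relabeling except within an
        absorption-step tie (two cut clusters merging with each other,
        resolved by the lowest node index, which relabeling changes); such
        a tie can only swap adjacent ranks.
        """
        F = random_connectivity(rng, 7)
        perm = rng.permutation(7)
        base = assign_classes(
            agglomerate_distances(connection_cluster_distances(F)), 4)
        permuted = assign_classes(
            agglomerate_distances(
                connection_cluster_distances(F[np.ix_(perm, perm)])), 4)

        def groups(assignment):
            out = {}
            for node, cls in assignment.labels.items():
                out.setdefault(cls, set()).add(node)
            return out

        g_base, g_perm = groups(base), groups(permuted)
        relabel = {orig + 1: new_pos for new_pos, orig in enumerate(perm, 1)}
        mapped = {cls: frozenset(relabel[n] for n in nodes)
                  for cls, nodes in g_base.items()}
        # the partition itself is equivariant
        assert {frozenset(s) for s in g_perm.values()} == set(mapped.values())
        # rank order is preserved whenever absorption steps differ: merge
        # distances are permutation-invariant, so a cluster's class can move
        # only within its absorption tie group, and a tie group holds at
        # most the two clusters absorbed by one merge (adjacent ranks)
        perm_cls = {frozenset(s): c for c, s in g_perm.items()}
        for cls_a in mapped:
            for cls_b in mapped:
                if cls_a < cls_b and perm_cls[mapped[cls_a]] > perm_cls[mapped[cls_b]]:
                    assert cls_b - cls_a == 1

    def test_scaling_leaves_classes_unchanged(self, rng):
        F = random_connectivity(rng, 6)
        a = assign_classes(agglomerate(node_vectors(F)), 4)
        b = assign_classes(agglomerate(node_vectors(0.1 * F)), 4)
        assert a.labels == b.labels


class TestTrajectory:
    def test_constant_assignments_give_constant_rows(self):
        a = ClassAssignment({1: 2, 2: 1, 3: 2}, 2)
        traj = class_trajectory([a, a, a])
        np.testing.assert_array_equal(traj, [[2, 2, 2], [1, 1, 1], [2, 2, 2]])

    def test_single_segment(self):
        a = ClassAssignment({1: 1, 2: 2}, 2)
        np.testing.assert_array_equal(class_trajectory([a]), [[1], [2]])

    def test_node_set_mismatch_rejected(self):
        a = ClassAssignment({1: 1, 2: 2}, 2)
        b = ClassAssignment({1: 1, 2: 2, 3: 1}, 2)
        with pytest.raises(ValueError):
            class_trajectory([a, b])


class TestLouvain:
    @staticmethod
    def two_cliques(k: int) -> np.ndarray:
        n = 2 * k
        v = np.zeros((n, n))
        v[:k, :k] = 1.0
        v[k:, k:] = 1.0
        np.fill_diagonal(v, 0.0)
        return v

    def test_two_disconnected_cliques(self):
        mapping, q = louvain_communities(self.two_cliques(4), seed=3)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len({mapping[i] for i in range(1, 5)}) == 1
        assert len({mapping[i] for i in range(5, 9)}) == 1
        assert mapping[1] != mapping[5]

    def test_complete_uniform_graph_single_community_q_zero(self):
        v = np.ones((6, 6)) - np.eye(6)
        q = modularity_brute(v, {i: 0 for i in range(1, 7)})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_partition_q_matches_brute_force(self, rng):
        for _ in range(10):
            v = random_connectivity(rng, 8)
            mapping, q = louvain_communities(v, seed=11)
            assert q == pytest.approx(modularity_brute(v, mapping), abs=1e-12)

    def test_edgeless_matrix_single_community(self):
        mapping, q = louvain_communities(np.zeros((4, 4)), seed=0)
        assert set(mapping.values()) == {0} and q == 0.0

    def test_deterministic_given_seed(self, rng):
        v = random_connectivity(rng, 10)
        assert louvain_communities(v, seed=7) == louvain_communities(v, seed=7)


class TestAlignedDistances:
    def test_matches_explicit_third_node_sum(self, rng):
        F = random_connectivity(rng, 6)
        D = connection_cluster_distances(F)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert D[i, j] == 0.0
                    continue
                expected = np.sqrt(sum(
                    (F[i, k] - F[j, k]) ** 2
                    for k in range(6) if k not in (i, j)))
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self, rng):
        F = random_connectivity(rng, 7)
        perm = rng.permutation(7)
        D = connection_cluster_distances(F)
        Dp = connection_cluster_distances(F[np.ix_(perm, perm)])
        np.testing.assert_allclose(Dp, D[np.ix_(perm, perm)], atol=1e-12)

    def test_classifier_merge_sequence_matches_naive_oracle(self, rng):
        for _ in range(30):
            F = random_connectivity(rng, 6)
            D = connection_cluster_distances(F)
            dend = agglomerate_distances(D, "single")
            ours = [(m.step, m.left, m.right, m.new) for m in dend.merges]
            oracle = [(s, a, b, new) for s, a, b, new, _ in
                      naive_agglomerate(linkage="single", base_dist=D)]
            assert ours == oracle


class TestClassifier:
    def test_labels_match_functional_route(self, rng):
        F = random_connectivity(rng, 8)
        clf = ConnectionClusterClassifier(n_classes=4).fit(F)
        expected = assign_classes(
            agglomerate_distances(connection_cluster_distances(F)), 4)
        np.testing.assert_array_equal(clf.labels_, expected.as_array())

    def test_fit_on_connectivity_matrix_carries_labels(self, rng):
        labels = ("Fp1", "Fp2", "F3", "F4")
        F = ConnectivityMatrix(labels, random_connectivity(rng, 4))
        clf = ConnectionClusterClassifier(n_classes=2).fit(F)
        assert set(clf.assignment_.by_channel()) == set(labels)

    def test_z_equals_n_gives_singletons(self, rng):
        F = random_connectivity(rng, 6)
        clf = ConnectionClusterClassifier(n_classes=6).fit(F)
        assert sorted(clf.labels_) == [1, 2, 3, 4, 5, 6]

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        clf = ConnectionClusterClassifier(n_classes=3, linkage="complete")
        assert clone(clf).get_params() == clf.get_params()

    def test_asymmetric_input_rejected(self, rng):
        X = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError):
            ConnectionClusterClassifier().fit(X)
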