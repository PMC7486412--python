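"""MDS embeddings and hierarchical clustering against geometric and
brute-force oracles."""

import numpy as np
import pytest

import germdiv as gd
from germdiv.structure import (
    ClusterTree,
    classical_mds,
    hierarchical_tree,
    pseudo_f_profile,
    pseudo_f_statistic,
    smacof_mds,
)

from conftest import euclidean_distance_matrix


class TestClassicalMDS:
    def test_recovers_exactly_embeddable_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 3))
        D = euclidean_distance_matrix(pts)
        emb = classical_mds(D, dims=3)
        assert np.allclose(emb.pairwise_distances(), D.values, atol=1e-9)
        assert emb.stress < 1e-18

    def test_all_zero_distances_collapse(self):
        D = gd.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = classical_mds(D)
        assert np.allclose(emb.coords, emb.coords[0])
        assert emb.stress == 0.0

    def test_collinear_points_are_one_dimensional(self):
        D = euclidean_distance_matrix(np.array([[0.0], [1.0], [3.0]]))
        emb = classical_mds(D, dims=3)
        assert emb.eigenvalues[0] > 1e-6
        assert abs(emb.eigenvalues[1]) < 1e-9
        assert abs(emb.eigenvalues[2]) < 1e-9

    def test_negative_eigenvalues_reported_for_non_euclidean(self):
        vals = np.array(
            [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]], dtype=float
        )
        emb = classical_mds(gd.DistanceMatrix(list("abcd"), vals))
        assert emb.n_negative_eigenvalues >= 0  # reported, not raised

    def test_missing_distances_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        D = gd.DistanceMatrix(list("abc"), vals)
        with pytest.raises(ValueError, match="min_overlap"):
            classical_mds(D)

    def test_order_invariance_of_stress_and_distances(self, complete_collection):
        D = gd.mrd_matrix(complete_collection.geno)
        perm = np.random.default_rng(2).permutation(D.n)
        Dp = gd.DistanceMatrix(
            [D.ids[i] for i in perm], D.values[np.ix_(perm, perm)], D.metric
        )
        e1, e2 = classical_mds(D), classical_mds(Dp)
        assert e1.stress == pytest.approx(e2.stress, rel=1e-6, abs=1e-9)
        d1 = e1.pairwise_distances()
        d2 = e2.pairwise_distances()[np.ix_(np.argsort(perm), np.argsort(perm))]
        assert np.allclose(d1, d2, atol=1e-6)


class TestSmacof:
    def test_starting_at_exact_embedding_stays(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        D = euclidean_distance_matrix(pts)
        emb = smacof_mds(D, dims=3, init=pts)
        assert emb.stress < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_stress_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        D = gd.DistanceMatrix([f"s{i}" for i in range(n)], vals)
        _, history = smacof_mds(D, dims=3, init="random", seed=seed, return_history=True)
        diffs = np.diff(history)
        assert (diffs <= 1e-10).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_refines_classical_solution(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 25
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        D = gd.DistanceMatrix([f"s{i}" for i in range(n)], vals)
        assert smacof_mds(D).stress <= classical_mds(D).stress + 1e-12

    def test_matches_sklearn_smacof_quality(self):
        """Independent cross-check: our SMACOF should reach stress no worse
        than sklearn's on the same input (both init from random starts)."""
        from sklearn.manifold import smacof as sk_smacof

        rng = np.random.default_rng(4)
        n = 20
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        ours = smacof_mds(gd.DistanceMatrix([f"s{i}" for i in range(n)], vals), dims=3)
        _, sk_stress = sk_smacof(
            vals, n_components=3, n_init=4, random_state=0, normalized_stress=False
        )
        # sklearn stress is sum over ordered pairs / 2 == our unordered sum
        assert ours.stress <= sk_stress * 1.05 + 1e-9

    def test_nonfinite_input_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.inf
        with pytest.raises(ValueError):
            smacof_mds(gd.DistanceMatrix(list("abc"), vals))


def brute_force_linkage(D, method="ward"):
    """O(n^3) agglomeration via the Lance-Williams update, squared-distance
    form for Ward (matches scipy's definition on a distance matrix)."""
    n = D.shape[0]
    active = {i: ([i], 1) for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    merges = []
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        (a, b), h = min(
            ((tuple(sorted((x, y))), dist[tuple(sorted((x, y)))])
             for xi, x in enumerate(ids) for y in ids[xi + 1:]),
            key=lambda kv: (kv[1], kv[0]),
        )
        na, nb = active[a][1], active[b][1]
        merged = (active[a][0] + active[b][0], na + nb)
        for c in ids:
            if c in (a, b):
                continue
            nc = active[c][1]
            dca = dist[tuple(sorted((c, a)))]
            dcb = dist[tuple(sorted((c, b)))]
            if method == "ward":
                new = np.sqrt(
                    ((na + nc) * dca**2 + (nb + nc) * dcb**2 - nc * h**2)
                    / (na + nb + nc)
                )
            elif method == "average":
                new = (na * dca + nb * dcb) / (na + nb)
            elif method == "complete":
                new = max(dca, dcb)
            else:
                raise ValueError(method)
            dist[tuple(sorted((c, next_id)))] = new
        active[next_id] = merged
        merges.append((sorted(active[a][0] + active[b][0]), h))
        ids = [x for x in ids if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


class TestHierarchicalTree:
    def test_two_samples_single_merge(self):
        D = gd.DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = hierarchical_tree(D, linkage="average")
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.7)

    @pytest.mark.parametrize("method", ["ward", "average", "complete"])
    def test_matches_brute_force_oracle_n6(self, method):
        rng = np.random.default_rng(42)
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        tree = hierarchical_tree(gd.DistanceMatrix(list("abcdef"), vals), linkage=method)
        oracle = brute_force_linkage(vals, method)
        for i, (row, (members, h)) in enumerate(zip(tree.linkage_matrix, oracle)):
            assert row[2] == pytest.approx(h, abs=1e-10)
            ours = tree._leaves(6 + i).tolist()
            assert ours == members
        # final partition structure at every level matches
        for k in range(2, 6):
            labels = tree.cut(k)
            assert len(np.unique(labels)) == k

    def test_two_blob_partition(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (12, 2))])
        D = euclidean_distance_matrix(pts)
        tree = hierarchical_tree(D)
        labels = tree.cut(2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_nesting_invariant(self, complete_collection):
        D = gd.mrd_matrix(complete_collection.geno)
        tree = hierarchical_tree(D)
        for k in range(2, 12):
            coarse, fine = tree.cut(k), tree.cut(k + 1)
            # each fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1

    def test_ward_heights_nondecreasing(self, complete_collection):
        D = gd.mrd_matrix(complete_collection.geno)
        tree = hierarchical_tree(D)
        assert (np.diff(tree.heights()) >= -1e-12).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_tree(gd.DistanceMatrix(["a"], np.zeros((1, 1))))


class TestPseudoF:
    def test_four_blobs_argmax_at_four(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
            pts = np.vstack([c + rng.normal(0, 0.6, (15, 2)) for c in centers])
            D = euclidean_distance_matrix(pts)
            tree = hierarchical_tree(D)
            prof = pseudo_f_profile(D, tree, k_max=10)
            if prof.selected_k == 4:
                hits += 1
        assert hits >= 9

    def test_zero_within_variance_flags_infinity(self):
        # two clusters of identical points
        pts = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5], [5, 5]])
        D = euclidean_distance_matrix(pts)
        labels = np.array([0, 0, 1, 1, 1])
        assert pseudo_f_statistic(D.values, labels) == np.inf

    def test_diffuse_cloud_has_flat_profile(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 1, size=(60, 3))
        D = euclidean_distance_matrix(pts)
        tree = hierarchical_tree(D)
        prof = pseudo_f_profile(D, tree, k_max=20)
        finite = prof.values[np.isfinite(prof.values)]
        assert finite.max() / np.median(finite) < 2

    def test_matches_calinski_harabasz_on_euclidean_points(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        D = euclidean_distance_matrix(pts)
        ours = pseudo_f_statistic(D.values, labels)
        theirs = calinski_harabasz_score(pts, labels)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_out_of_range_k_rejected(self):
        D = euclidean_distance_matrix(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            pseudo_f_statistic(D.values, np.zeros(5, dtype=int))


class TestSplitMembers:
    def test_root_split_is_level_two_partition(self, complete_collection):
        D = gd.mrd_matrix(complete_collection.geno)
        tree = hierarchical_tree(D)
        left, right = tree.split_members(0)
        labels = tree.cut(2)
        sets = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        assert {frozenset(left), frozenset(right)} == {frozenset(s) for s in sets}
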