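"""The three candidate-cluster generators and their building blocks."""

import logging

import numpy as np
import pytest

from clustersim import (
    UNASSIGNED,
    ConfigurationError,
    HDBSCANConfig,
    PartialAssignment,
    PLKMeansConfig,
    RejectionStore,
    SKMeansConfig,
    hdbscan_candidates,
    kmeans_base,
    pl_kmeans,
    shrink_clusters,
    shrunken_kmeans,
)


def _two_blobs(n_per=50, dist=50.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal([0.0, 0.0], 0.5, size=(n_per, 2)),
            rng.normal([dist, 0.0], 0.5, size=(n_per, 2)),
        ]
    )
    return X


class TestKMeansBase:
    def test_separates_two_blobs_exactly(self):
        X = _two_blobs()
        asg = kmeans_base(X, k=2, seed=1)
        # brute-force nearest-center check after convergence
        centroids = np.vstack([asg.centroids[0], asg.centroids[1]])
        nearest = np.argmin(
            np.linalg.norm(X[:, None, :] - centroids[None], axis=2), axis=1
        )
        np.testing.assert_array_equal(asg.labels, nearest)
        assert len(set(asg.labels[:50])) == 1 and len(set(asg.labels[50:])) == 1
        assert asg.labels[0] != asg.labels[50]

    def test_identical_points_single_cluster(self):
        X = np.ones((20, 3)) * 2.5
        asg = kmeans_base(X, k=1, seed=0)
        np.testing.assert_allclose(asg.centroids[0], [2.5, 2.5, 2.5])
        assert asg.n_assigned == 20

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2)) * 10
        asg = kmeans_base(X, k=12, seed=3)
        assert len(asg.cluster_ids) == 12
        for cid in asg.cluster_ids:
            m = asg.members(cid)
            assert len(m) == 1
            np.testing.assert_allclose(X[m[0]], asg.centroids[cid])

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ConfigurationError, match="k"):
            kmeans_base(np.zeros((3, 2)), k=4)


class TestShrink:
    def test_p_core_one_is_identity(self):
        X = _two_blobs()
        asg = kmeans_base(X, k=2, seed=0)
        out = shrink_clusters(asg, X, p_core=1.0)
        np.testing.assert_array_equal(out.labels, asg.labels)

    def test_keeps_nearest_half_on_a_line(self):
        # 10 collinear points; centroid forced to their mean
        X = np.array([[float(i), 0.0] for i in range(10)])
        asg = PartialAssignment(
            labels=np.zeros(10, dtype=int), centroids={0: X.mean(axis=0)}
        )
        out = shrink_clusters(asg, X, p_core=0.5)
        kept = np.flatnonzero(out.labels == 0)
        assert sorted(kept) == [2, 3, 4, 5, 6]  # 5 points nearest to x=4.5, tie at ids
        assert (out.labels[[0, 1, 8, 9]] == UNASSIGNED).all()

    def test_retention_floor_single_member(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 3))
        asg = PartialAssignment(labels=np.zeros(7, dtype=int))
        out = shrink_clusters(asg, X, p_core=0.01)
        assert (out.labels != UNASSIGNED).sum() == 1
        # the survivor is the point nearest the member mean (brute force)
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        assert out.labels[np.argmin(d)] == 0

    def test_never_increases_max_member_distance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        asg = kmeans_base(X, k=5, seed=5)
        out = shrink_clusters(asg, X, p_core=0.3)
        for cid in asg.cluster_ids:
            before = np.linalg.norm(X[asg.members(cid)] - asg.centroids[cid], axis=1).max()
            kept = out.members(cid)
            after = np.linalg.norm(X[kept] - asg.centroids[cid], axis=1).max()
            assert after <= before + 1e-12


class TestShrunkenKMeans:
    def test_retention_counts_four_blobs(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [100, 0], [0, 100], [100, 100]], dtype=float)
        X = np.vstack([rng.normal(c, 0.5, size=(100, 2)) for c in centers])
        asg = shrunken_kmeans(X, SKMeansConfig(k=4, p_core=0.1, seed=2))
        sizes = sorted(len(asg.members(c)) for c in asg.cluster_ids)
        assert sizes == [10, 10, 10, 10]
        assert (asg.labels == UNASSIGNED).sum() == 360

    def test_singleton_floor_when_k_equals_n(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 2)) * 10
        asg = shrunken_kmeans(X, SKMeansConfig(k=15, p_core=0.01, seed=9))
        assert asg.n_assigned == 15

    def test_p_core_one_equals_kmeans_base(self):
        X = _two_blobs(seed=4)
        a = shrunken_kmeans(X, SKMeansConfig(k=3, p_core=1.0, seed=7))
        b = kmeans_base(X, k=3, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)


def _empty_prior(n):
    return PartialAssignment(labels=np.full(n, UNASSIGNED, dtype=np.int64))


class TestPLKMeans:
    def test_vacuous_constraints_equal_kmeans_base(self):
        X = _two_blobs(seed=6)
        cfg = PLKMeansConfig(k0=4, k_delta=7, p_noise=0.0, p_core=1.0, seed=11)
        a = pl_kmeans(X, _empty_prior(len(X)), RejectionStore(), cfg, outer_iteration=0)
        b = kmeans_base(X, k=4, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rejection_forces_second_nearest_cluster(self):
        # two validated singleton-ish clusters; a free point nearer cluster 0
        # but rejected for it must land in cluster 1
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0], [1.0, 0.0]])
        prior = PartialAssignment(
            labels=np.array([0, 0, 1, 1, UNASSIGNED]),
            centroids={0: X[:2].mean(0), 1: X[2:4].mean(0)},
        )
        rej = RejectionStore.from_pairs([(4, 0)])
        cfg = PLKMeansConfig(k0=2, k_delta=0, p_noise=0.0, p_core=1.0, seed=0)
        out = pl_kmeans(X, prior, rej, cfg, outer_iteration=0)
        assert out.labels[4] == 1

    def test_rejected_everywhere_stays_unassigned(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 0.0]])
        prior = PartialAssignment(
            labels=np.array([0, 1, UNASSIGNED]), centroids={0: X[0], 1: X[1]}
        )
        rej = RejectionStore.from_pairs([(2, 0), (2, 1)])
        cfg = PLKMeansConfig(k0=2, k_delta=0, p_noise=0.0, p_core=1.0, seed=0)
        out = pl_kmeans(X, prior, rej, cfg, outer_iteration=0)
        assert out.labels[2] == UNASSIGNED

    def test_validated_members_never_move_and_new_blob_forms_cluster(self):
        rng = np.random.default_rng(13)
        a = rng.normal([0, 0], 0.3, size=(20, 2))
        b = rng.normal([50, 0], 0.3, size=(20, 2))
        c = rng.normal([25, 40], 0.3, size=(100, 2))
        X = np.vstack([a, b, c])
        labels = np.array([0] * 20 + [1] * 20 + [UNASSIGNED] * 100)
        prior = PartialAssignment(
            labels=labels, centroids={0: a.mean(0), 1: b.mean(0)}
        )
        cfg = PLKMeansConfig(k0=3, k_delta=0, p_noise=0.0, p_core=1.0, seed=1)
        out = pl_kmeans(X, prior, RejectionStore(), cfg, outer_iteration=0)
        np.testing.assert_array_equal(out.labels[:40], labels[:40])
        new = set(out.labels[40:])
        assert len(new) == 1 and new.pop() == 2

    def test_cluster_count_schedule(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(80, 3)) * 20
        cfg = PLKMeansConfig(k0=5, k_delta=3, p_noise=0.0, p_core=1.0, seed=2)
        for i in (0, 1, 2):
            out = pl_kmeans(X, _empty_prior(80), RejectionStore(), cfg, outer_iteration=i)
            assert len(out.cluster_ids) == 5 + 3 * i

    def test_k_clamped_to_free_objects(self, caplog):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(6, 2))
        cfg = PLKMeansConfig(k0=10, k_delta=0, p_noise=0.0, p_core=1.0, seed=0)
        with caplog.at_level(logging.WARNING):
            out = pl_kmeans(X, _empty_prior(6), RejectionStore(), cfg)
        assert len(out.cluster_ids) <= 6
        assert any("clamping" in r.message for r in caplog.records)

    def test_shrinking_spares_validated_clusters(self):
        rng = np.random.default_rng(23)
        a = rng.normal([0, 0], 0.3, size=(30, 2))
        c = rng.normal([40, 40], 0.3, size=(40, 2))
        X = np.vstack([a, c])
        prior = PartialAssignment(
            labels=np.array([0] * 30 + [UNASSIGNED] * 40), centroids={0: a.mean(0)}
        )
        cfg = PLKMeansConfig(k0=2, k_delta=0, p_noise=0.1, p_core=0.1, seed=3)
        out = pl_kmeans(X, prior, RejectionStore(), cfg)
        assert len(out.members(0)) >= 30  # intact (may even absorb)
        assert len(out.members(1)) == 4  # ceil(0.1 * 40)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(29)
        X = rng.normal(size=(60, 4))
        cfg = PLKMeansConfig(k0=6, k_delta=0, p_noise=0.1, p_core=0.5, seed=8)
        a = pl_kmeans(X, _empty_prior(60), RejectionStore(), cfg)
        b = pl_kmeans(X, _empty_prior(60), RejectionStore(), cfg)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestHDBSCANAdapter:
    def test_three_blobs_with_noise(self):
        rng = np.random.default_rng(31)
        blobs = [
            rng.normal(c, 0.5, size=(200, 2))
            for c in ([0, 0], [50, 0], [0, 50])
        ]
        noise = rng.uniform(-25, 75, size=(50, 2))
        X = np.vstack(blobs + [noise])
        truth = np.repeat([0, 1, 2], 200)
        # leaf selection needs a minimum cluster size large enough that a
        # single Gaussian blob cannot split into two leaves
        asg = hdbscan_candidates(X, HDBSCANConfig(neighborhood_k=8, m0=32))
        blob_labels = asg.labels[:600]
        assert (blob_labels != UNASSIGNED).mean() > 0.95
        # each generating blob maps to exactly one found cluster
        for b in range(3):
            found = blob_labels[truth == b]
            found = found[found != UNASSIGNED]
            assert len(set(found)) == 1
        assert (asg.labels[600:] == UNASSIGNED).mean() > 0.5

    def test_fewer_points_than_minimum_cluster_size(self, caplog):
        X = np.zeros((5, 2))
        with caplog.at_level(logging.WARNING):
            asg = hdbscan_candidates(X, HDBSCANConfig(neighborhood_k=2, m0=16))
        assert (asg.labels == UNASSIGNED).all()
        assert any("fewer" in r.message for r in caplog.records)

    def test_decay_reaches_floor_of_two(self):
        rng = np.random.default_rng(37)
        X = np.vstack(
            [rng.normal([0, 0], 0.01, size=(3, 2)), rng.normal([10, 0], 0.01, size=(3, 2))]
        )
        # m0 * 0.5**10 << 2, so the floor applies and tiny clusters are legal
        asg = hdbscan_candidates(X, HDBSCANConfig(neighborhood_k=1, m0=128), outer_iteration=10)
        assert len(asg.cluster_ids) >= 1
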