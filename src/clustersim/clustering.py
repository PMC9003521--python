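"""Candidate-cluster generators returning partial (non-exhaustive) assignments.

The annotation simulator needs clusterers that label only the densest regions
and leave uncertain objects unassigned, so that cluster validation stays cheap
and growing does the bulk of the work. Three generators are provided:

* shrunken k-means: plain k-means followed by a shrinking step that keeps only
  the fraction ``p_core`` of members closest to each centroid;
* partially labeled k-means (PL-k-means): a constrained Lloyd iteration that
  freezes objects in already-validated clusters (positive information), bars
  free objects from clusters they were rejected for via the Boolean rejection
  matrix R (negative information), recomputes each centroid from only the
  ``1 - p_noise`` fraction of members closest to the previous center, and
  finally shrinks newly formed clusters with ``p_core``;
* an adapter around HDBSCAN* with leaf cluster selection and an exponentially
  decaying minimum cluster size across outer iterations.

All distances are Euclidean, matching the similarity search used during
cluster growing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .data import (
    UNASSIGNED,
    ConfigurationError,
    PartialAssignment,
    RejectionStore,
)

logger = logging.getLogger(__name__)

# Guards ceil() against binary float artifacts of decimal quantiles,
# e.g. 0.1 * 100 = 10.000000000000002.
_CEIL_EPS = 1e-9


@dataclass
class SKMeansConfig:
    """Shrunken k-means parameters (defaults follow the reference tool setup:
    k=1000 clusters, core quantile p_core=0.01)."""

    k: int = 1000
    p_core: float = 0.01
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be a positive integer")
        if not 0 < self.p_core <= 1:
            raise ConfigurationError("p_core must lie in (0, 1]")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be a positive integer")


@dataclass
class PLKMeansConfig:
    """Partially labeled k-means parameters.

    The total cluster count at outer iteration ``i`` is ``k0 + i * k_delta``,
    so later rounds look for more and smaller clusters. Defaults follow the
    reference setup: k0=500, k_delta=100, p_noise=0.1, p_core=0.01.
    """

    k0: int = 500
    k_delta: int = 100
    p_noise: float = 0.1
    p_core: float = 0.01
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ConfigurationError("k0 must be a positive integer")
        if self.k_delta < 0:
            raise ConfigurationError("k_delta must be >= 0")
        if not 0 <= self.p_noise < 1:
            raise ConfigurationError("p_noise must lie in [0, 1)")
        if not 0 < self.p_core <= 1:
            raise ConfigurationError("p_core must lie in (0, 1]")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be a positive integer")


@dataclass
class HDBSCANConfig:
    """HDBSCAN* adapter parameters.

    ``neighborhood_k`` is the core-distance neighborhood size (min_samples),
    ``m0`` the initial minimum cluster size. The minimum cluster size decays
    by ``decay_factor`` per outer iteration, floored at 2, so that later
    rounds can still carve clusters out of an ever smaller pool.
    """

    neighborhood_k: int = 8
    m0: int = 128
    decay_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.neighborhood_k < 1:
            raise ConfigurationError("neighborhood_k must be >= 1")
        if self.m0 < 2:
            raise ConfigurationError("m0 must be >= 2")
        if not 0 < self.decay_factor <= 1:
            raise ConfigurationError("decay_factor must lie in (0, 1]")


def _retention_count(p: float, m: int) -> int:
    """Members kept by a quantile rule: max(1, ceil(p * m))."""
    return max(1, math.ceil(p * m - _CEIL_EPS))


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 weighting); falls back to uniform choice among
    unchosen points once all residual distances are zero."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    chosen = np.zeros(n, dtype=bool)
    i = int(rng.integers(n))
    centers[0] = X[i]
    chosen[i] = True
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            i = int(rng.choice(n, p=d2 / total))
        else:
            i = int(rng.choice(np.flatnonzero(~chosen)))
        centers[j] = X[i]
        chosen[i] = True
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


LloydCallback = Callable[[int, np.ndarray, np.ndarray], None]


def _lloyd(
    X: np.ndarray,
    centroids: np.ndarray,
    *,
    frozen: np.ndarray | None = None,
    forbidden: np.ndarray | None = None,
    p_noise: float = 0.0,
    max_iter: int = 100,
    callback: Optional[LloydCallback] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained Lloyd iteration over columns of ``centroids``.

    frozen
        Per-object column index or -1; frozen objects never change column
        ("positive information" from validated clusters).
    forbidden
        Boolean (n, k) mask; True bars an object from a column ("negative
        information" from the rejection matrix). An object barred from every
        column stays UNASSIGNED.
    p_noise
        Fraction of most-distant members excluded when recomputing each
        centroid, measured against the previous center.
    callback
        Called after every expectation step as ``callback(step, centroids,
        labels)`` with the centroids that produced the assignment.

    Empty columns are re-seeded with the assigned point farthest from its own
    centroid, keeping the requested cluster count alive. Iteration stops when
    the assignment is stable or after ``max_iter`` rounds.
    """
    n, _ = X.shape
    k = centroids.shape[0]
    centroids = centroids.copy()
    prev_labels: np.ndarray | None = None
    reseeded = False
    labels = np.full(n, UNASSIGNED, dtype=np.int64)

    for step in range(max_iter):
        D = cdist(X, centroids)
        if forbidden is not None:
            D[forbidden] = np.inf
        labels = np.asarray(np.argmin(D, axis=1), dtype=np.int64)
        finite = np.isfinite(D[np.arange(n), labels])
        labels[~finite] = UNASSIGNED
        if frozen is not None:
            f = frozen >= 0
            labels[f] = frozen[f]
        if callback is not None:
            callback(step, centroids.copy(), labels.copy())
        if prev_labels is not None and not reseeded and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels

        # maximization step
        reseeded = False
        used_reseeds: list[int] = []
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if len(members) == 0:
                i = _reseed_point(X, D, labels, frozen, forbidden, j, used_reseeds)
                if i is not None:
                    centroids[j] = X[i]
                    used_reseeds.append(i)
                    reseeded = True
                continue
            if p_noise > 0.0 and len(members) > 1:
                dist_prev = np.linalg.norm(X[members] - centroids[j], axis=1)
                keep = _retention_count(1.0 - p_noise, len(members))
                members = members[np.argsort(dist_prev, kind="stable")[:keep]]
            centroids[j] = X[members].mean(axis=0)

    return labels, centroids


def _reseed_point(
    X: np.ndarray,
    D: np.ndarray,
    labels: np.ndarray,
    frozen: np.ndarray | None,
    forbidden: np.ndarray | None,
    j: int,
    used: list[int],
) -> int | None:
    """Pick the assigned, movable point farthest from its current centroid."""
    eligible = labels >= 0
    if frozen is not None:
        eligible &= frozen < 0
    if forbidden is not None:
        eligible &= ~forbidden[:, j]
    if used:
        eligible[used] = False
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return None
    own = D[idx, labels[idx]]
    return int(idx[np.argmax(own)])


def kmeans_base(
    features: np.ndarray,
    k: int,
    init_centroids: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> PartialAssignment:
    """Plain Lloyd k-means with k-means++ seeding; every object is assigned.

    This is the exhaustive baseline both k-means variants build on.
    """
    X = np.asarray(features, dtype=np.float64)
    if k > X.shape[0]:
        raise ConfigurationError(f"k = {k} exceeds the number of objects n = {X.shape[0]}")
    if k < 1:
        raise ConfigurationError("k must be a positive integer")
    if init_centroids is None:
        rng = np.random.default_rng(seed)
        init_centroids = _kmeanspp(X, k, rng)
    labels, centroids = _lloyd(X, np.asarray(init_centroids, dtype=np.float64), max_iter=max_iter)
    return PartialAssignment(
        labels=labels, centroids={j: centroids[j] for j in range(k)}
    )


def shrink_clusters(
    assignment: PartialAssignment,
    features: np.ndarray,
    p_core: float,
    only_clusters: set[int] | None = None,
) -> PartialAssignment:
    """Reduce every cluster to its core: the ``max(1, ceil(p_core * m))``
    members closest to the centroid keep their label, ties broken by ascending
    object id; all other members become UNASSIGNED.

    Centroids are deliberately not recomputed: the core is a subsample of the
    cluster, not a new cluster. With ``p_core = 1.0`` the assignment is
    returned unchanged. ``only_clusters`` restricts shrinking to the given
    cluster ids (used by PL-k-means, which leaves validated clusters intact).
    """
    if not 0 < p_core <= 1:
        raise ConfigurationError("p_core must lie in (0, 1]")
    X = np.asarray(features, dtype=np.float64)
    labels = assignment.labels.copy()
    ids = np.asarray(assignment.object_ids).astype(str)
    for cid in assignment.cluster_ids:
        if only_clusters is not None and cid not in only_clusters:
            continue
        members = assignment.members(cid)
        keep = _retention_count(p_core, len(members))
        if keep >= len(members):
            continue
        centroid = assignment.centroid(cid, X)
        dist = np.linalg.norm(X[members] - centroid, axis=1)
        # lexsort: primary key distance, secondary key ascending object id
        order = np.lexsort((ids[members], dist))
        labels[members[order[keep:]]] = UNASSIGNED
    return PartialAssignment(
        labels=labels,
        centroids=dict(assignment.centroids),
        object_ids=assignment.object_ids,
    )


def shrunken_kmeans(features: np.ndarray, config: SKMeansConfig) -> PartialAssignment:
    """k-means followed by cluster shrinking (S-k-means).

    The unassigned fraction is approximately ``1 - p_core`` for balanced
    clusters; with ``p_core = 1.0`` the result equals plain k-means.
    """
    base = kmeans_base(features, config.k, seed=config.seed, max_iter=config.max_iter)
    return shrink_clusters(base, features, config.p_core)


def pl_kmeans(
    features: np.ndarray,
    prior: PartialAssignment,
    rejections: RejectionStore,
    config: PLKMeansConfig,
    outer_iteration: int = 0,
    callback: Optional[Callable[[int, list[int], np.ndarray, np.ndarray], None]] = None,
) -> PartialAssignment:
    """Partially labeled k-means over ``k0 + outer_iteration * k_delta`` clusters.

    Objects carrying a validated label in ``prior`` keep it throughout; free
    objects are assigned to the nearest centroid among clusters they were not
    rejected for (an object rejected for every cluster stays UNASSIGNED).
    Validated clusters may absorb so-far-unclustered objects ("late
    assignment"). Centroids are recomputed from the ``1 - p_noise`` fraction
    of members closest to the previous center. After convergence the shrinking
    step is applied to newly formed clusters only; validated clusters are
    returned intact.

    ``callback(step, cluster_ids, centroids, labels)`` fires after each
    expectation step with centroid rows aligned to ``cluster_ids`` and labels
    in cluster-id space, exposing every Lloyd step to external checks.
    """
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if prior.n != n:
        raise ConfigurationError("prior assignment does not cover the feature rows")

    validated_ids = prior.cluster_ids
    for cid in validated_ids:
        for i in prior.members(cid):
            if rejections.is_rejected(int(i), cid):
                raise ConfigurationError(
                    f"object {i} carries a validated label for cluster {cid} "
                    "but is also rejected for it"
                )
    v = len(validated_ids)
    free = np.flatnonzero(prior.labels == UNASSIGNED)
    n_free = len(free)

    k_total = config.k0 + outer_iteration * config.k_delta
    n_new = k_total - v
    if n_new < 0:
        logger.warning(
            "requested k = %d is below the %d validated clusters; no new clusters",
            k_total, v,
        )
        n_new = 0
    if n_new > n_free:
        logger.warning(
            "requested %d new clusters but only %d free objects; clamping",
            n_new, n_free,
        )
        n_new = n_free

    next_id = (max(validated_ids) + 1) if validated_ids else 0
    new_ids = [next_id + t for t in range(n_new)]
    column_ids: list[int] = list(validated_ids) + new_ids
    k = len(column_ids)
    if k == 0:
        return PartialAssignment(
            labels=np.full(n, UNASSIGNED, dtype=np.int64),
            centroids={},
            object_ids=prior.object_ids,
        )

    centroids = np.empty((k, X.shape[1]))
    for col, cid in enumerate(validated_ids):
        centroids[col] = prior.centroid(cid, X)
    if n_new > 0:
        rng = np.random.default_rng(config.seed)
        centroids[v:] = _kmeanspp(X[free], n_new, rng)

    frozen = np.full(n, -1, dtype=np.int64)
    for col, cid in enumerate(validated_ids):
        frozen[prior.members(cid)] = col

    forbidden = None
    if v > 0 and len(rejections) > 0:
        forbidden = np.zeros((n, k), dtype=bool)
        col_of = {cid: col for col, cid in enumerate(validated_ids)}
        for obj, cid in rejections.pairs():
            col = col_of.get(cid)
            if col is not None:
                forbidden[obj, col] = True

    inner_callback = None
    if callback is not None:
        def inner_callback(step: int, cents: np.ndarray, labs: np.ndarray) -> None:
            mapped = np.full(n, UNASSIGNED, dtype=np.int64)
            for col, cid in enumerate(column_ids):
                mapped[labs == col] = cid
            callback(step, list(column_ids), cents, mapped)

    labels_col, final_centroids = _lloyd(
        X,
        centroids,
        frozen=frozen,
        forbidden=forbidden,
        p_noise=config.p_noise,
        max_iter=config.max_iter,
        callback=inner_callback,
    )

    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    for col, cid in enumerate(column_ids):
        labels[labels_col == col] = cid
    result = PartialAssignment(
        labels=labels,
        centroids={cid: final_centroids[col] for col, cid in enumerate(column_ids)},
        object_ids=prior.object_ids,
    )
    return shrink_clusters(result, X, config.p_core, only_clusters=set(new_ids))


def hdbscan_candidates(
    features: np.ndarray, config: HDBSCANConfig, outer_iteration: int = 0
) -> PartialAssignment:
    """HDBSCAN* with leaf cluster selection as a partial clusterer.

    The minimum cluster size is ``max(2, round(m0 * decay_factor**i))`` at
    outer iteration ``i``; density noise points are returned UNASSIGNED and
    centroids are member means.
    """
    from sklearn.cluster import HDBSCAN

    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    mcs = max(2, int(round(config.m0 * config.decay_factor**outer_iteration)))
    if n < mcs or n <= config.neighborhood_k:
        logger.warning(
            "%d points is fewer than the minimum cluster size %d; nothing clustered",
            n, mcs,
        )
        return PartialAssignment(labels=np.full(n, UNASSIGNED, dtype=np.int64))

    model = HDBSCAN(
        min_cluster_size=mcs,
        min_samples=config.neighborhood_k,
        cluster_selection_method="leaf",
        copy=True,
    )
    raw = model.fit_predict(X)
    labels = np.asarray(raw, dtype=np.int64)
    centroids = {
        int(cid): X[labels == cid].mean(axis=0)
        for cid in np.unique(labels)
        if cid != UNASSIGNED
    }
    return PartialAssignment(labels=labels, centroids=centroids)


# ---------------------------------------------------------------------------
# Adapters plugging the clusterers into the annotation simulation loop.
# ---------------------------------------------------------------------------


@dataclass
class Proposal:
    """What a clusterer proposes for one simulation iteration.

    ``new_clusters`` are member-index lists (global dataset indices) of
    candidate clusters awaiting validation. ``late_assignments`` maps a
    validated cluster id to pool objects the clusterer assigned to it directly
    (only PL-k-means produces these).
    """

    new_clusters: list[np.ndarray] = field(default_factory=list)
    late_assignments: dict[int, np.ndarray] = field(default_factory=dict)


def _derive_seed(seed: int, iteration: int) -> int:
    return int(np.random.SeedSequence([seed, iteration]).generate_state(1)[0] % (2**31))


class ShrunkenKMeansClusterer:
    """Clusters the unassigned pool with S-k-means each iteration."""

    name = "skmeans"

    def __init__(self, config: SKMeansConfig):
        self.config = config

    def propose(self, features: np.ndarray, state, iteration: int) -> Proposal:
        pool = np.array(sorted(state.pool), dtype=np.int64)
        if len(pool) == 0:
            return Proposal()
        k = self.config.k
        if k > len(pool):
            logger.warning("k = %d clamped to pool size %d", k, len(pool))
            k = len(pool)
        cfg = SKMeansConfig(
            k=k,
            p_core=self.config.p_core,
            max_iter=self.config.max_iter,
            seed=_derive_seed(self.config.seed, iteration),
        )
        asg = shrunken_kmeans(features[pool], cfg)
        return Proposal(new_clusters=[pool[asg.members(c)] for c in asg.cluster_ids])


class PLKMeansClusterer:
    """Re-clusters the whole dataset, freezing validated clusters and
    honoring the accumulated rejection matrix."""

    name = "plkmeans"

    def __init__(self, config: PLKMeansConfig):
        self.config = config

    def propose(self, features: np.ndarray, state, iteration: int) -> Proposal:
        n = features.shape[0]
        labels = np.full(n, UNASSIGNED, dtype=np.int64)
        centroids: dict[int, np.ndarray] = {}
        for cid in sorted(state.clusters):
            cluster = state.clusters[cid]
            labels[np.asarray(cluster.members, dtype=np.int64)] = cid
            centroids[cid] = cluster.centroid
        prior = PartialAssignment(labels=labels, centroids=centroids)
        cfg = PLKMeansConfig(
            k0=self.config.k0,
            k_delta=self.config.k_delta,
            p_noise=self.config.p_noise,
            p_core=self.config.p_core,
            max_iter=self.config.max_iter,
            seed=_derive_seed(self.config.seed, iteration),
        )
        asg = pl_kmeans(features, prior, state.rejections, cfg, outer_iteration=iteration)
        new_clusters = []
        late: dict[int, np.ndarray] = {}
        for cid in asg.cluster_ids:
            members = asg.members(cid)
            if cid in state.clusters:
                old = set(state.clusters[cid].members)
                added = np.array([i for i in members if i not in old], dtype=np.int64)
                if len(added):
                    late[cid] = added
            else:
                new_clusters.append(members)
        return Proposal(new_clusters=new_clusters, late_assignments=late)


class HDBSCANClusterer:
    """Clusters the unassigned pool with HDBSCAN* (leaf selection), decaying
    the minimum cluster size across iterations."""

    name = "hdbscan"

    def __init__(self, config: HDBSCANConfig):
        self.config = config

    def propose(self, features: np.ndarray, state, iteration: int) -> Proposal:
        pool = np.array(sorted(state.pool), dtype=np.int64)
        if len(pool) == 0:
            return Proposal()
        asg = hdbscan_candidates(features[pool], self.config, outer_iteration=iteration)
        return Proposal(new_clusters=[pool[asg.members(c)] for c in asg.cluster_ids])
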