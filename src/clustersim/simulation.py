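"""Simulated human-in-the-loop annotation on clustered embeddings.

The simulator replays the interactive annotation workflow against gold
labels: candidate clusters are validated by purity against a threshold
``t_v``; accepted clusters are then grown by scanning the unclustered pool in
order of distance to the cluster centroid, in batches, using exponential and
binary search over the (assumed monotone) fitting/non-fitting boundary,
followed by a linear scan once mixed batches appear. Every simulated user
interaction (cluster decision, batch probe, single-object removal) costs one
click; the click ledger is the cost unit of the efficiency metric.

The simulated user is a threshold oracle on the gold labels; human error,
fatigue and label ambiguity are deliberately not modeled.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import ConfigurationError, EmbeddingSet, RejectionStore

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Thresholds and loop controls of the simulated annotator.

    Defaults follow the interactive application: validation purity threshold
    t_v = 0.85, pure-batch threshold t_gp = 0.75, unpure-batch threshold
    t_gu = 0.55 and a hard-coded batch size of 50 candidates. A cluster that
    grew by more than ``regrow_trigger`` times its size at the start of a
    growing pass has its centroid recomputed and growing restarted, at most
    ``max_regrows`` times per cluster per iteration.
    """

    t_v: float = 0.85
    t_gp: float = 0.75
    t_gu: float = 0.55
    batch_size: int = 50
    max_iterations: int = 12
    completeness_stop: float = 0.99
    regrow_trigger: float = 1.0
    max_regrows: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.t_v < 1:
            raise ConfigurationError("t_v must lie in (0, 1)")
        if not 0 < self.t_gu <= self.t_gp < 1:
            raise ConfigurationError("thresholds must satisfy 0 < t_gu <= t_gp < 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class Cluster:
    """A validated cluster: member indices, centroid, and the majority gold
    label determined at validation time (what the simulated user believes the
    cluster shows)."""

    members: list[int]
    centroid: np.ndarray
    label: str


@dataclass
class SimulationState:
    """Mutable state of one simulated annotation run.

    ``clusters`` (validated) plus ``candidates`` (awaiting validation) plus
    ``pool`` always partition the object indices. Cluster ids increase
    monotonically and are never reused, so a rejection recorded for a deleted
    cluster can never apply to a later one.
    """

    n: int
    clusters: dict[int, Cluster] = field(default_factory=dict)
    candidates: dict[int, list[int]] = field(default_factory=dict)
    pool: set[int] = field(default_factory=set)
    rejections: RejectionStore = field(default_factory=RejectionStore)
    clicks: Counter = field(default_factory=Counter)
    iteration: int = 0
    _next_cluster_id: int = 0

    @classmethod
    def initial(cls, n: int) -> "SimulationState":
        return cls(n=n, pool=set(range(n)))

    def new_cluster_id(self) -> int:
        cid = self._next_cluster_id
        self._next_cluster_id += 1
        return cid

    @property
    def total_clicks(self) -> int:
        return sum(self.clicks.values())

    @property
    def n_assigned(self) -> int:
        return sum(len(c.members) for c in self.clusters.values())

    def assignment_labels(self) -> np.ndarray:
        """Per-object validated cluster id, -1 for pool/candidate objects."""
        labels = np.full(self.n, -1, dtype=np.int64)
        for cid, cluster in self.clusters.items():
            labels[np.asarray(cluster.members, dtype=np.int64)] = cid
        return labels

    def check_partition(self) -> None:
        counted: set[int] = set(self.pool)
        total = len(self.pool)
        for members in self.candidates.values():
            counted.update(members)
            total += len(members)
        for cluster in self.clusters.values():
            counted.update(cluster.members)
            total += len(cluster.members)
        if total != self.n or len(counted) != self.n:
            raise AssertionError("clusters, candidates and pool do not partition the objects")


def cluster_purity(member_labels: Sequence) -> tuple[float, str]:
    """Fraction of members matching the majority gold label.

    Majority ties are broken by the lexicographically smallest label.
    """
    labels = [str(l) for l in member_labels]
    if len(labels) == 0:
        raise ValueError("cluster_purity of an empty member sequence is undefined")
    counts = Counter(labels)
    best = max(counts.values())
    majority = min(l for l, c in counts.items() if c == best)
    return best / len(labels), majority


def validate_clusters(
    state: SimulationState,
    features: np.ndarray,
    gold: np.ndarray,
    config: SimulationConfig,
) -> SimulationState:
    """Simulated validation of all candidate clusters (in cluster-id order).

    A candidate with purity >= t_v is accepted (1 click); its non-majority
    members are removed to the pool, one click and one rejection record each,
    and the centroid is recomputed from the survivors. A candidate below t_v
    is deleted wholesale (1 click) and every member returns to the pool with
    a rejection record for the deleted cluster.
    """
    for cid in sorted(state.candidates):
        members = state.candidates.pop(cid)
        purity, majority = cluster_purity(gold[members])
        if purity >= config.t_v:
            state.clicks["validation"] += 1
            survivors = []
            for i in members:
                if str(gold[i]) == majority:
                    survivors.append(i)
                else:
                    state.rejections.add(i, cid)
                    state.pool.add(i)
                    state.clicks["validation"] += 1
            centroid = features[np.asarray(survivors, dtype=np.int64)].mean(axis=0)
            state.clusters[cid] = Cluster(
                members=survivors, centroid=centroid, label=majority
            )
        else:
            state.clicks["validation"] += 1
            for i in members:
                state.rejections.add(i, cid)
                state.pool.add(i)
    return state


def exponential_search_boundary(
    accept: Callable[[int], bool],
    n_batches: int,
    on_probe: Callable[[int], None] | None = None,
) -> int:
    """Smallest rejected 1-based batch index under a monotone accept oracle.

    Probes positions 1, 2, 4, 8, ... (clamped to ``n_batches``) until a probe
    is rejected or the list ends, then binary-searches the open interval
    between the last accepted and the first rejected probe. Returns
    ``n_batches + 1`` if every batch is accepted. ``on_probe`` fires once per
    probe (the click hook).
    """
    if n_batches <= 0:
        return 1
    lo, hi = 0, None  # last accepted / first rejected
    idx = 1
    while True:
        if on_probe is not None:
            on_probe(idx)
        if accept(idx):
            lo = idx
            if idx == n_batches:
                return n_batches + 1
            idx = min(2 * idx, n_batches)
        else:
            hi = idx
            break
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if on_probe is not None:
            on_probe(mid)
        if accept(mid):
            lo = mid
        else:
            hi = mid
    return hi


class _LinearSwitch(Exception):
    """Raised inside the boundary search when a mixed batch flips the grower
    into linear scanning mode."""

    def __init__(self, index: int):
        self.index = index


def grow_cluster(
    cluster_id: int,
    state: SimulationState,
    features: np.ndarray,
    gold: np.ndarray,
    config: SimulationConfig,
) -> SimulationState:
    """Grow one validated cluster by batch-wise similarity search.

    Candidates are the pool objects without a rejection record for this
    cluster, ordered by increasing Euclidean distance to the centroid (ties by
    object index) and cut into batches of ``batch_size``. Batch purity is
    measured against the cluster's validated majority label:

    * purity >= t_gp: the batch fits and is accepted whole (1 click);
    * t_gu <= purity < t_gp: the batch is accepted after removing the
      non-matching objects (1 click + 1 click and a rejection record per
      removal) and the search switches to linear scanning;
    * purity < t_gu: the batch is rejected (1 click), all its objects receive
      a rejection record, and the search interval shrinks.

    The fitting/non-fitting boundary is located with
    :func:`exponential_search_boundary`; unprobed batches inside the accepted
    region join the cluster unseen, which is where the approach trades a
    little precision for efficiency. If the cluster grew by more than
    ``regrow_trigger`` times its size at the start of the pass, the centroid
    is recomputed and growing restarts (at most ``max_regrows`` times).
    """
    cluster = state.clusters[cluster_id]
    regrows = 0
    while True:
        pre_size = len(cluster.members)
        added = _grow_pass(cluster_id, state, features, gold, config)
        if added == 0:
            break
        cluster.centroid = features[
            np.asarray(cluster.members, dtype=np.int64)
        ].mean(axis=0)
        if added > config.regrow_trigger * pre_size and regrows < config.max_regrows:
            regrows += 1
            continue
        break
    return state


def _grow_pass(
    cluster_id: int,
    state: SimulationState,
    features: np.ndarray,
    gold: np.ndarray,
    config: SimulationConfig,
) -> int:
    """One growing pass; returns the number of objects added."""
    cluster = state.clusters[cluster_id]
    pool = np.array(
        [i for i in sorted(state.pool) if not state.rejections.is_rejected(i, cluster_id)],
        dtype=np.int64,
    )
    if len(pool) == 0:
        return 0
    dist = np.linalg.norm(features[pool] - cluster.centroid, axis=1)
    order = np.lexsort((pool, dist))
    ranked = pool[order]
    b = config.batch_size
    batches = [ranked[s : s + b] for s in range(0, len(ranked), b)]
    n_batches = len(batches)

    purity_of: dict[int, float] = {}
    removals: dict[int, list[int]] = {}

    def probe(idx: int) -> float:
        batch = batches[idx - 1]
        state.clicks["growing"] += 1
        matches = sum(1 for i in batch if str(gold[i]) == cluster.label)
        p = matches / len(batch)
        purity_of[idx] = p
        return p

    def search_accept(idx: int) -> bool:
        p = probe(idx)
        if p >= config.t_gp:
            return True
        if p >= config.t_gu:
            raise _LinearSwitch(idx)
        for i in batches[idx - 1]:
            state.rejections.add(int(i), cluster_id)
        return False

    linear_from: int | None = None
    try:
        boundary = exponential_search_boundary(search_accept, n_batches)
        accepted_upto = boundary - 1
    except _LinearSwitch as switch:
        accepted_upto = switch.index
        linear_from = switch.index + 1
        removals[switch.index] = _remove_mismatches(
            batches[switch.index - 1], cluster, state, gold, cluster_id
        )

    if linear_from is not None:
        for idx in range(linear_from, n_batches + 1):
            p = probe(idx)
            if p >= config.t_gp:
                accepted_upto = idx
            elif p >= config.t_gu:
                accepted_upto = idx
                removals[idx] = _remove_mismatches(
                    batches[idx - 1], cluster, state, gold, cluster_id
                )
            else:
                for i in batches[idx - 1]:
                    state.rejections.add(int(i), cluster_id)
                break

    added = 0
    for idx in range(1, accepted_upto + 1):
        removed = set(removals.get(idx, ()))
        for i in batches[idx - 1]:
            i = int(i)
            if i in removed:
                continue
            state.pool.discard(i)
            cluster.members.append(i)
            added += 1
    return added


def _remove_mismatches(
    batch: np.ndarray,
    cluster: Cluster,
    state: SimulationState,
    gold: np.ndarray,
    cluster_id: int,
) -> list[int]:
    """Individual removal of non-matching objects from a mixed batch: one
    click and one rejection record per removed object."""
    removed = []
    for i in batch:
        i = int(i)
        if str(gold[i]) != cluster.label:
            state.clicks["growing"] += 1
            state.rejections.add(i, cluster_id)
            removed.append(i)
    return removed


def run_simulation(
    dataset: EmbeddingSet,
    clusterer,
    config: SimulationConfig,
) -> tuple[SimulationState, list[dict]]:
    """Alternate cluster -> validate -> grow until a stop criterion is met.

    ``clusterer`` is any object with a
    ``propose(features, state, iteration) -> Proposal`` method (see the
    adapters in :mod:`clustersim.clustering`). The rejection store is carried
    across iterations; PL-k-means consumes it, the other clusterers ignore it.
    The loop stops at ``max_iterations``, when completeness reaches
    ``completeness_stop``, or when an iteration assigns zero new objects.

    Returns the final state and a per-iteration trace with the objects sorted
    and clicks spent per phase, suitable for progress curves.
    """
    if dataset.gold_labels is None:
        raise ConfigurationError("run_simulation requires gold labels")
    gold = dataset.gold_labels
    features = dataset.features
    state = SimulationState.initial(dataset.n)
    trace: list[dict] = []

    for iteration in range(config.max_iterations):
        state.iteration = iteration
        assigned_before = state.n_assigned
        clicks_v_before = state.clicks["validation"]
        clicks_g_before = state.clicks["growing"]

        proposal = clusterer.propose(features, state, iteration)

        # late assignment: pool objects attached directly to validated clusters
        for cid in sorted(proposal.late_assignments):
            cluster = state.clusters[cid]
            for i in proposal.late_assignments[cid]:
                i = int(i)
                if i in state.pool:
                    state.pool.discard(i)
                    cluster.members.append(i)

        new_ids = []
        for members in proposal.new_clusters:
            cid = state.new_cluster_id()
            members = [int(i) for i in members if i in state.pool]
            if not members:
                continue
            for i in members:
                state.pool.discard(i)
            state.candidates[cid] = members
            new_ids.append(cid)

        validate_clusters(state, features, gold, config)
        for cid in new_ids:
            if cid in state.clusters:
                grow_cluster(cid, state, features, gold, config)

        assigned_now = state.n_assigned
        trace.append(
            {
                "iteration": iteration,
                "objects_assigned": assigned_now - assigned_before,
                "cumulative_assigned": assigned_now,
                "clicks_validation": state.clicks["validation"] - clicks_v_before,
                "clicks_growing": state.clicks["growing"] - clicks_g_before,
            }
        )
        if assigned_now - assigned_before == 0:
            logger.info("iteration %d assigned no objects; stopping", iteration)
            break
        if assigned_now / dataset.n >= config.completeness_stop:
            logger.info("completeness target reached after iteration %d", iteration)
            break
    return state, trace
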