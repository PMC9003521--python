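"""Evaluation measures for a finished simulation or a raw assignment.

Four antagonistic metrics summarize an annotation run: efficiency (objects
sorted per click), completeness (fraction of objects assigned), precision
(unweighted mean over clusters of the fraction of members matching the
cluster's majority gold label) and the final number of clusters. NCC-F1, the
F1 score of a nearest centroid classifier on held-out data, measures how
compact and well-separated the gold classes are in a representation space —
the premise the whole clustering approach rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestCentroid

from .data import EmbeddingSet
from .simulation import SimulationState, cluster_purity

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    efficiency: float
    completeness: float
    precision: Optional[float]
    n_clusters: int
    ncc_f1: Optional[float] = None
    runtime_seconds: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "efficiency": self.efficiency,
            "completeness": self.completeness,
            "precision": self.precision,
            "n_clusters": self.n_clusters,
            "ncc_f1": self.ncc_f1,
            "runtime_seconds": self.runtime_seconds,
        }


def efficiency(n_sorted: int, n_clicks: int) -> float:
    """Objects sorted per virtual click; 0 for an empty run."""
    if n_clicks < 0:
        raise ValueError("n_clicks must be >= 0")
    if n_clicks == 0:
        if n_sorted == 0:
            return 0.0
        raise ValueError("objects cannot be sorted without clicks")
    return n_sorted / n_clicks


def completeness(state: SimulationState) -> float:
    """Fraction of all objects assigned to validated clusters."""
    return state.n_assigned / state.n


def precision(state: SimulationState, gold: np.ndarray) -> Optional[float]:
    """Unweighted mean over clusters of the majority-label fraction.

    Returns None when there are no clusters (undefined). An object-weighted
    variant is available as :func:`precision_weighted`.
    """
    purities = [
        cluster_purity(gold[np.asarray(c.members, dtype=np.int64)])[0]
        for c in state.clusters.values()
    ]
    if not purities:
        return None
    return float(np.mean(purities))


def precision_weighted(state: SimulationState, gold: np.ndarray) -> Optional[float]:
    """Object-weighted counterpart of :func:`precision`."""
    total = matched = 0
    for c in state.clusters.values():
        p, _ = cluster_purity(gold[np.asarray(c.members, dtype=np.int64)])
        total += len(c.members)
        matched += p * len(c.members)
    if total == 0:
        return None
    return matched / total


def ncc_f1(train: EmbeddingSet, test: EmbeddingSet, average: str = "macro") -> float:
    """F1 score of a nearest centroid classifier fit on ``train``.

    Class centroids are per-class means of the training features; test
    objects are predicted by the nearest centroid (Euclidean). Macro averaging
    over classes is the default (micro available via ``average``). A test
    class absent from training scores 0 with a logged warning.
    """
    if train.gold_labels is None or test.gold_labels is None:
        raise ValueError("ncc_f1 requires gold labels on both sets")
    train_labels = train.gold_labels.astype(str)
    test_labels = test.gold_labels.astype(str)
    missing = set(np.unique(test_labels)) - set(np.unique(train_labels))
    if missing:
        logger.warning(
            "%d test label(s) absent from the training set score 0", len(missing)
        )
    if len(np.unique(train_labels)) == 1:
        pred = np.full(test.n, np.unique(train_labels)[0])
    else:
        clf = NearestCentroid(metric="euclidean")
        clf.fit(train.features, train_labels)
        pred = clf.predict(test.features)
    classes = sorted(set(np.unique(test_labels)) | set(np.unique(train_labels)))
    return float(
        f1_score(test_labels, pred, labels=classes, average=average, zero_division=0)
    )


def compute_report(
    state: SimulationState,
    gold: np.ndarray,
    ncc: Optional[float] = None,
    runtime_seconds: Optional[float] = None,
) -> MetricsReport:
    """Bundle the run-level metrics from a finished simulation state."""
    return MetricsReport(
        efficiency=efficiency(state.n_assigned, state.total_clicks),
        completeness=completeness(state),
        precision=precision(state, gold),
        n_clusters=len(state.clusters),
        ncc_f1=ncc,
        runtime_seconds=runtime_seconds,
    )
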