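"""Core data containers shared by all stages.

The simulator operates on a fixed embedding dataset (:class:`EmbeddingSet`),
produces non-exhaustive cluster assignments (:class:`PartialAssignment`) and
accumulates object-cluster incompatibilities (:class:`RejectionStore`) that
later clustering rounds can consume as cannot-link information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Sentinel cluster label meaning "object belongs to the unclustered pool".
UNASSIGNED: int = -1


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class DimensionalityError(ValueError):
    """A requested dimensionality is incompatible with the data shape."""


class FormatError(ValueError):
    """An input file violates the expected on-disk format."""


@dataclass
class EmbeddingSet:
    """An ``n x d`` feature matrix with object identifiers and optional gold labels.

    Parameters
    ----------
    object_ids
        Unique opaque identifiers, one per row of ``features``.
    features
        Real-valued matrix of shape ``(n, d)``; typically deep-learning image
        representations reduced to a few tens of dimensions.
    gold_labels
        Optional expert annotation per object. The simulator uses these as the
        oracle for every accept/reject decision; they are hidden from the
        clustering algorithms themselves.
    """

    object_ids: np.ndarray
    features: np.ndarray
    gold_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.object_ids = np.asarray(self.object_ids)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise FormatError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if n < 1:
            raise FormatError("an EmbeddingSet needs at least one object")
        if self.object_ids.shape[0] != n:
            raise FormatError(
                f"{self.object_ids.shape[0]} object ids but {n} feature rows"
            )
        if len(np.unique(self.object_ids)) != n:
            raise FormatError("object_ids must be distinct")
        bad = ~np.isfinite(self.features)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise FormatError(f"non-finite feature value in row {row}")
        if self.gold_labels is not None:
            self.gold_labels = np.asarray(self.gold_labels)
            if self.gold_labels.shape[0] != n:
                raise FormatError(
                    f"{self.gold_labels.shape[0]} gold labels but {n} objects"
                )
            if any(len(str(l)) == 0 for l in self.gold_labels):
                raise FormatError("gold labels must be non-empty")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: Sequence[int]) -> "EmbeddingSet":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices)
        return EmbeddingSet(
            object_ids=self.object_ids[idx],
            features=self.features[idx],
            gold_labels=None if self.gold_labels is None else self.gold_labels[idx],
        )


@dataclass
class PartialAssignment:
    """Per-object cluster label where ``UNASSIGNED`` is a first-class value.

    ``labels[i]`` is the integer cluster id of object ``i`` or ``UNASSIGNED``.
    ``centroids`` maps cluster ids to d-vectors; for density-based clusterings
    centroids are the member means, computed when the assignment is built.
    """

    labels: np.ndarray
    centroids: dict[int, np.ndarray] = field(default_factory=dict)
    object_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.object_ids is None:
            self.object_ids = np.array(
                [f"{i}" for i in range(len(self.labels))], dtype=object
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def cluster_ids(self) -> list[int]:
        """Sorted ids of non-empty clusters."""
        ids = np.unique(self.labels)
        return [int(c) for c in ids if c != UNASSIGNED]

    @property
    def n_assigned(self) -> int:
        return int((self.labels != UNASSIGNED).sum())

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def centroid(self, cluster_id: int, features: np.ndarray) -> np.ndarray:
        """Stored centroid, or the member mean if none was stored."""
        if cluster_id in self.centroids:
            return self.centroids[cluster_id]
        m = self.members(cluster_id)
        if len(m) == 0:
            raise KeyError(f"cluster {cluster_id} has no members and no centroid")
        return features[m].mean(axis=0)

    @property
    def cluster_of(self) -> dict:
        """Mapping object_id -> cluster id (or None for UNASSIGNED)."""
        return {
            oid: (None if lab == UNASSIGNED else int(lab))
            for oid, lab in zip(self.object_ids, self.labels)
        }


class RejectionStore:
    """Sparse Boolean relation R over (object, cluster) pairs.

    ``R[i, j] = True`` records that object ``i`` was found not to belong to
    cluster ``j`` during validation or growing. Unset pairs are False. The
    store is consumed by partially labeled k-means as cannot-link information.
    Objects are addressed by integer row index, clusters by integer cluster id.
    """

    def __init__(self) -> None:
        self._by_object: dict[int, set[int]] = {}

    def add(self, obj: int, cluster_id: int) -> None:
        self._by_object.setdefault(int(obj), set()).add(int(cluster_id))

    def is_rejected(self, obj: int, cluster_id: int) -> bool:
        return int(cluster_id) in self._by_object.get(int(obj), ())

    def rejected_clusters(self, obj: int) -> frozenset[int]:
        return frozenset(self._by_object.get(int(obj), ()))

    def pairs(self) -> Iterator[tuple[int, int]]:
        for obj in sorted(self._by_object):
            for cid in sorted(self._by_object[obj]):
                yield obj, cid

    def __len__(self) -> int:
        return sum(len(s) for s in self._by_object.values())

    def copy(self) -> "RejectionStore":
        new = RejectionStore()
        new._by_object = {k: set(v) for k, v in self._by_object.items()}
        return new

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[int, int]]) -> "RejectionStore":
        store = cls()
        for obj, cid in pairs:
            store.add(obj, cid)
        return store
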