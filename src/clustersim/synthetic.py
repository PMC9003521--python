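"""Synthetic embedding datasets with the structure the simulator assumes.

The nearest-centroid premise behind the annotation simulator is that a good
representation space holds dense, well-separated, roughly spherical classes
of equal variance. This module generates exactly such mixtures with
controllable class count, imbalance, separation, diffuse background noise
and optional sub-class structure, so every downstream stage can be exercised
without any real image data. It also provides the PCA preprocessing step used
to bring high-dimensional deep features down to a workable dimensionality
(d=32 by default in the real pipeline) and a stratified train/test split for
nearest-centroid evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from .data import ConfigurationError, DimensionalityError, EmbeddingSet

logger = logging.getLogger(__name__)

#: Within-class standard deviation of the generated Gaussians. The separation
#: parameter is a ratio relative to this scale, so the absolute value is
#: arbitrary; it is fixed at 1 to keep coordinates dimensionless.
WITHIN_CLASS_STD: float = 1.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic mixture.

    separation is the ratio of the minimum pairwise distance between class
    centers to the within-class standard deviation; 10 gives essentially
    non-overlapping classes in low dimensions. noise_fraction is the share of
    the final dataset made up of diffuse background points, each carrying a
    unique singleton gold label so that no clusterer can legitimately group
    them. subclass_split_fraction splits that share of classes into two
    half-separated Gaussians whose gold labels share a parent prefix,
    emulating interchangeable sub-classes in real annotations.
    """

    n_classes: int = 20
    objects_per_class: int | list[int] = 100
    d: int = 32
    separation: float = 10.0
    noise_fraction: float = 0.0
    subclass_split_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be a positive integer")
        sizes = self.class_sizes()
        if len(sizes) != self.n_classes or any(s < 1 for s in sizes):
            raise ConfigurationError(
                "objects_per_class must be positive (one value or one per class)"
            )
        if self.d < 1:
            raise ConfigurationError("d must be a positive integer")
        if not self.separation > 0:
            raise ConfigurationError("separation must be > 0")
        if not 0 <= self.noise_fraction < 1:
            raise ConfigurationError("noise_fraction must lie in [0, 1)")
        if not 0 <= self.subclass_split_fraction <= 1:
            raise ConfigurationError("subclass_split_fraction must lie in [0, 1]")

    def class_sizes(self) -> list[int]:
        if isinstance(self.objects_per_class, int):
            return [self.objects_per_class] * self.n_classes
        return [int(s) for s in self.objects_per_class]


def _class_centers(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Random centers rescaled so min pairwise distance equals the target.

    Centers are drawn from an isotropic Gaussian and then scaled as a whole so
    that the minimum pairwise center distance is exactly
    ``separation * WITHIN_CLASS_STD``. Drawing directions first and rescaling
    afterwards makes the well-separated regime a controlled parameter instead
    of an accident of sampling.
    """
    k, d = config.n_classes, config.d
    if k == 1:
        return np.zeros((1, d))
    centers = rng.standard_normal((k, d))
    dmin = pdist(centers).min()
    while dmin == 0.0:  # astronomically unlikely; regenerate
        centers = rng.standard_normal((k, d))
        dmin = pdist(centers).min()
    return centers * (config.separation * WITHIN_CLASS_STD / dmin)


def generate_embeddings(config: GeneratorConfig) -> EmbeddingSet:
    """Draw a synthetic :class:`EmbeddingSet` with gold labels.

    Deterministic: identical config (including seed) gives bit-identical
    output. Class centers satisfy
    ``min pairwise distance >= separation * within-class std``.
    """
    rng = np.random.default_rng(config.seed)
    sigma = WITHIN_CLASS_STD
    centers = _class_centers(config, rng)
    sizes = config.class_sizes()

    n_split = int(round(config.subclass_split_fraction * config.n_classes))

    feats: list[np.ndarray] = []
    labels: list[str] = []
    for c, (center, size) in enumerate(zip(centers, sizes)):
        base = f"class_{c:03d}"
        if c < n_split:
            # Two half-separated sub-blobs: sub-center distance is half the
            # between-class separation, so sub-classes overlap more with each
            # other than with any foreign class.
            u = rng.standard_normal(config.d)
            u /= np.linalg.norm(u)
            offset = u * (config.separation * sigma / 4.0)
            n_a = (size + 1) // 2
            for sub, sub_center, m in (
                ("a", center + offset, n_a),
                ("b", center - offset, size - n_a),
            ):
                if m > 0:
                    feats.append(sub_center + sigma * rng.standard_normal((m, config.d)))
                    labels.extend([f"{base}/{sub}"] * m)
        else:
            feats.append(center + sigma * rng.standard_normal((size, config.d)))
            labels.extend([base] * size)

    n_signal = sum(sizes)
    f = config.noise_fraction
    n_noise = int(round(f / (1.0 - f) * n_signal)) if f > 0 else 0
    if n_noise > 0:
        # Diffuse background: uniform in the bounding box of the centers,
        # inflated by twice the within-class std, one singleton label each.
        lo = centers.min(axis=0) - 2.0 * sigma
        hi = centers.max(axis=0) + 2.0 * sigma
        feats.append(rng.uniform(lo, hi, size=(n_noise, config.d)))
        labels.extend(f"noise_{i:05d}" for i in range(n_noise))

    features = np.vstack(feats)
    n = features.shape[0]
    object_ids = np.array([f"obj{i:06d}" for i in range(n)], dtype=object)
    return EmbeddingSet(
        object_ids=object_ids,
        features=features,
        gold_labels=np.array(labels, dtype=object),
    )


def pca_reduce(features: np.ndarray, d: int) -> np.ndarray:
    """Project ``features`` onto the top ``d`` principal components.

    The input is mean-centered before projection; components are ordered by
    decreasing explained variance. No whitening is applied, so when
    ``d == D`` the map is an orthogonal rotation that preserves pairwise
    Euclidean distances.
    """
    features = np.asarray(features, dtype=np.float64)
    n, D = features.shape
    if d > min(n, D):
        raise DimensionalityError(
            f"target dimensionality {d} exceeds min(n, D) = {min(n, D)}"
        )
    return PCA(n_components=d, svd_solver="full", whiten=False).fit_transform(features)


def split_train_test(
    dataset: EmbeddingSet, test_fraction: float, seed: int
) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Stratified train/test split by gold label.

    Classes too small to stratify (fewer than two members) are placed wholly
    in the training set with a logged warning. The two sides have disjoint id
    sets and their union equals the input.
    """
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    if dataset.gold_labels is None:
        raise ConfigurationError("split_train_test requires gold labels")

    labels = dataset.gold_labels
    uniq, counts = np.unique(labels, return_counts=True)
    singleton_classes = set(uniq[counts < 2])
    if singleton_classes:
        logger.warning(
            "%d class(es) with < 2 members placed wholly in the training set",
            len(singleton_classes),
        )
    eligible = np.array([lab not in singleton_classes for lab in labels])
    idx_eligible = np.flatnonzero(eligible)
    idx_single = np.flatnonzero(~eligible)

    train_idx, test_idx = train_test_split(
        idx_eligible,
        test_size=test_fraction,
        random_state=seed,
        stratify=labels[idx_eligible],
    )
    train_idx = np.sort(np.concatenate([train_idx, idx_single]))
    test_idx = np.sort(test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)
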