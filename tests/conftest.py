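"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from clustersim import EmbeddingSet, GeneratorConfig, generate_embeddings


@pytest.fixture
def blobs_2d():
    """Two tight, far-apart blobs of 50 points each in 2-D."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.5, size=(50, 2))
    b = rng.normal([100.0, 0.0], 0.5, size=(50, 2))
    features = np.vstack([a, b])
    labels = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
    ids = np.array([f"o{i:03d}" for i in range(100)], dtype=object)
    return EmbeddingSet(object_ids=ids, features=features, gold_labels=labels)


@pytest.fixture
def separated_classes():
    """Five well-separated classes of 100 points in 8-D."""
    return generate_embeddings(
        GeneratorConfig(n_classes=5, objects_per_class=100, d=8, separation=10, seed=7)
    )
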