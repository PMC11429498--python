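import numpy as np
import pytest

from abnet.graph import build_skeleton_graph, partition_adjacency
from abnet.io import SkeletonSequence
from abnet.synthetic import BEHAVIOR_CLASSES, SyntheticDatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph3():
    """3-joint path 0-1-2 with self-loops; degrees (2, 3, 2)."""
    return build_skeleton_graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def small_graph():
    """5-joint star-ish graph used for layer oracle tests."""
    g = build_skeleton_graph(5, [(0, 1), (1, 2), (1, 3), (3, 4)])
    partition_adjacency(g, "distance")
    return g


@pytest.fixture
def random_clip(rng):
    """One 20-frame 12-joint clip with valid conf channel."""
    data = rng.normal(size=(1, 3, 20, 12, 1))
    data[:, 2] = rng.uniform(0.5, 1.0, size=data[:, 2].shape)
    return SkeletonSequence(data)


@pytest.fixture(scope="session")
def tiny_two_class():
    """20 noiseless clips: movement vs standing — separable by design."""
    spec = SyntheticDatasetSpec(
        counts={"movement": 10, "standing": 10, "head_turning": 0, "turning": 0},
        anomaly_fraction=0.0,
        train_ratio=0.999,
        jitter_sd=0.0,
        seed=0,
    )
    train, _, _ = generate_dataset(spec)
    return train


@pytest.fixture(scope="session")
def labeled_dataset():
    """Small 4-class dataset with planted anomalies in the test split."""
    counts = {b: 10 for b in BEHAVIOR_CLASSES}
    spec = SyntheticDatasetSpec(counts=counts, anomaly_fraction=0.1, seed=7)
    return generate_dataset(spec)
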