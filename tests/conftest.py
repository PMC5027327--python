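import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neurotree.prep import PrepConfig, prepare
from neurotree.preprocess import FeatureTable, to_feature_table
from neurotree.simulate import config_for_profile, generate_recording
from neurotree.tree import DecisionTreeModel, TreeNode, TreeParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def leaf(counts) -> TreeNode:
    return TreeNode(class_counts=np.asarray(counts, dtype=float))


def small_config(seed=0, profile="sighted", **overrides):
    """A cheap recording config for property sweeps (short session, 128 Hz)."""
    defaults = dict(
        sampling_rate=128.0,
        baseline_band=(0.3, 50.0),
        epoch_schedule=(("ball", 1.0), ("interval", 1.0)),
    )
    defaults.update(overrides)
    return config_for_profile(profile, seed=seed, **defaults)


def make_table(class_sizes, n_channels=3, seed=0, channel_names=None):
    """A feature table with the given per-class instance counts, classes in
    contiguous blocks, random non-negative attribute values."""
    rng = np.random.default_rng(seed)
    labels = [c for c, k in class_sizes.items() for _ in range(k)]
    n = len(labels)
    names = list(channel_names) if channel_names else [f"ch{i}" for i in range(n_channels)]
    frame = pd.DataFrame(rng.uniform(0, 10, size=(n, len(names))), columns=names)
    frame.insert(0, "Time", np.arange(1, n + 1))
    frame["Class"] = labels
    return FeatureTable(frame)


@pytest.fixture
def example_tree() -> DecisionTreeModel:
    """Hand-built four-class object-handling tree splitting on Time and CP1.

    Structure: Time <= 14 -> cube; else Time <= 30 -> (CP1 <= 0.072 ->
    interval, else ball); else parallelogram.
    """
    classes = ("ball", "cube", "interval", "parallelogram")
    cube = leaf([0, 4, 0, 0])
    interval = leaf([0, 0, 4, 0])
    ball = leaf([4, 0, 0, 0])
    para = leaf([0, 0, 0, 4])
    cp1 = TreeNode(
        class_counts=np.array([4.0, 0, 4, 0]),
        split_attribute="CP1", threshold=0.072, left=interval, right=ball,
    )
    t30 = TreeNode(
        class_counts=np.array([4.0, 0, 4, 4]),
        split_attribute="Time", threshold=30.0, left=cp1, right=para,
    )
    root = TreeNode(
        class_counts=np.array([4.0, 4, 4, 4]),
        split_attribute="Time", threshold=14.0, left=cube, right=t30,
    )
    return DecisionTreeModel(
        root=root, classes=classes, attributes=("Time", "CP1"),
        params=TreeParams(), n_training=16,
    )


@pytest.fixture(scope="session")
def sighted_grouped() -> FeatureTable:
    """Full-pipeline grouped table for one simulated sighted subject."""
    rec = generate_recording(config_for_profile("sighted", seed=7))
    return prepare(to_feature_table(rec), PrepConfig(balance_seed=7))
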