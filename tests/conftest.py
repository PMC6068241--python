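"""Shared fixtures: small graphs and a compact planted-effect dataset."""

from __future__ import annotations

import numpy as np
import pytest

import wrsvmc as w


def random_graph(rng: np.random.Generator, n: int, p: float) -> w.BinaryGraph:
    """Erdos-Renyi binary graph with generic labels."""
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.int8)
    edges = rng.random(iu.size) < p
    adj[iu, ju] = edges
    adj[ju, iu] = edges
    return w.BinaryGraph(adj=adj, region_labels=[f"ROI_{k}" for k in range(n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def triangle() -> w.BinaryGraph:
    adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    return w.BinaryGraph(adj=adj, region_labels=["A", "B", "C"])


@pytest.fixture
def path3() -> w.BinaryGraph:
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return w.BinaryGraph(adj=adj, region_labels=["A", "B", "C"])


@pytest.fixture
def star4() -> w.BinaryGraph:
    """Center node 0 with 4 leaves."""
    adj = np.zeros((5, 5), dtype=int)
    adj[0, 1:] = 1
    adj[1:, 0] = 1
    return w.BinaryGraph(adj=adj, region_labels=list("CABDE"))


@pytest.fixture(scope="session")
def small_planted():
    """A compact planted-effect dataset plus its split and SVM settings.

    Small enough (12 ROIs, 15 per class) that ensemble tests stay fast.
    """
    cfg = w.SyntheticConfig(
        n_regions=12,
        n_per_class=15,
        planted_pairs=w.default_planted_pairs(6, 5),
        seed=42,
    )
    dataset = w.generate_dataset(cfg)
    split = w.split_dataset(dataset, n_train_val=19, seed=7)
    config = w.SvmConfig(n_train_samples=12, n_features=20)
    return cfg, dataset, split, config
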