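"""Shared fixtures: small canonical graphs and generated snapshots."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ppievo.graph_model import snapshot_from_edges

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def triangle():
    return snapshot_from_edges([("A", "B"), ("B", "C"), ("A", "C")], release_id="tri")


@pytest.fixture
def path4():
    """Path graph A-B-C-D."""
    return snapshot_from_edges([("A", "B"), ("B", "C"), ("C", "D")], release_id="path")


@pytest.fixture
def two_k5():
    """Two 5-cliques joined by a single bridge edge."""
    edges = []
    for names in ("abcde", "fghij"):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((names[i], names[j]))
    edges.append(("a", "f"))
    return snapshot_from_edges(edges, release_id="2k5")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_snapshot(rng: np.random.Generator, n: int = 50, p: float = 0.1):
    """Erdos-Renyi snapshot with deterministic node names."""
    names = [f"N{i:03d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    snap = snapshot_from_edges(edges, release_id=f"gnp{n}")
    for name in names:
        snap.add_node(name)
    return snap
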