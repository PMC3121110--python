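from __future__ import annotations

import numpy as np
import pytest

from nims import AgentProfile, BackgroundNetwork, PhenotypeSimilarity


@pytest.fixture
def path_net() -> BackgroundNetwork:
    """Path graph a-b-c-d-e."""
    return BackgroundNetwork([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def star_net() -> BackgroundNetwork:
    """Star K1,4 with center 'c'."""
    return BackgroundNetwork([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def two_components() -> BackgroundNetwork:
    """Two disconnected triangles."""
    return BackgroundNetwork(
        [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]
    )


@pytest.fixture
def uniform_sim() -> PhenotypeSimilarity:
    ids = ["p1", "p2", "p3"]
    mat = np.full((3, 3), 0.4)
    np.fill_diagonal(mat, 1.0)
    return PhenotypeSimilarity(ids, mat)


def random_network(rng: np.random.Generator, n_nodes: int, p: float = 0.2) -> BackgroundNetwork:
    """Erdős–Rényi network over string node ids (may be disconnected)."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return BackgroundNetwork(edges, nodes=nodes)


def make_agent(agent_id: str, genes, phenotypes=()) -> AgentProfile:
    return AgentProfile(agent_id, frozenset(genes), frozenset(phenotypes))
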