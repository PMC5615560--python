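from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from icarreg import AdjacencyGraph, build_grid_adjacency

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def path4() -> AdjacencyGraph:
    """Four nodes in a line: a - b - c - d."""
    return AdjacencyGraph.from_neighbours(
        {"a": {"b"}, "b": {"a", "c"}, "c": {"b", "d"}, "d": {"c"}},
        ["a", "b", "c", "d"],
    )


@pytest.fixture
def grid5() -> AdjacencyGraph:
    return build_grid_adjacency(5, 5, "rook")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250928)


def graph_edges(graph: AdjacencyGraph) -> list[tuple[int, int]]:
    """Undirected edge list as index pairs, for oracle routines."""
    out = []
    for i in graph.node_ids:
        ii = graph.index_of(i)
        for j in graph.neighbours[i]:
            jj = graph.index_of(j)
            if ii < jj:
                out.append((ii, jj))
    return out
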