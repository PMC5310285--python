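"""Shared builders for small deterministic test networks."""

from __future__ import annotations

import numpy as np
import pytest

from slnsrw.hetnet import HeteroNetwork


def make_net(
    n_nodes: int,
    edges: list[tuple[int, int, int, float]],
    K: int,
    node_types: list[str] | None = None,
) -> HeteroNetwork:
    """Build a network from (u, v, type_idx, t0) tuples."""
    eu, ev, et, t0 = zip(*edges) if edges else ((), (), (), ())
    return HeteroNetwork(
        node_ids=[f"x{i}" for i in range(n_nodes)],
        node_types=node_types or ["gene"] * n_nodes,
        edge_u=np.array(eu, dtype=np.intp),
        edge_v=np.array(ev, dtype=np.intp),
        edge_type=np.array(et, dtype=np.intp),
        t0=np.array(t0, dtype=float),
        evidence=[[] for _ in edges],
        edge_type_names=[f"type_{k}" for k in range(K)],
    )


def path_net(n: int, K: int = 1, t0: float = 1.0) -> HeteroNetwork:
    return make_net(n, [(i, i + 1, 0, t0) for i in range(n - 1)], K)


def star_net(m: int, K: int = 1, t0: float = 1.0) -> HeteroNetwork:
    """Center node 0 with m leaves."""
    return make_net(m + 1, [(0, i, 0, t0) for i in range(1, m + 1)], K)


def random_net(rng: np.random.Generator, n: int, K: int) -> HeteroNetwork:
    """Random connected network: spanning tree plus ~n/2 extra edges."""
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(v))
        edges.add((u, v))
    for _ in range(n // 2):
        u, v = rng.choice(n, size=2, replace=False)
        edges.add((min(u, v), max(u, v)))
    rows = [
        (u, v, int(rng.integers(K)), float(rng.uniform(0.2, 1.0)))
        for u, v in sorted(edges)
    ]
    return make_net(n, rows, K)


@pytest.fixture
def two_node_net() -> HeteroNetwork:
    return path_net(2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
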