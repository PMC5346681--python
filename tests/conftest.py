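"""Shared fixtures and independent oracles.

The betweenness oracle enumerates every shortest path explicitly (BFS
distances + backward path reconstruction), independent of the Brandes
accumulation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from ppibench import InteractionNetwork


# ------------------------------------------------------------- oracles


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def all_shortest_paths(adj: dict, s, t):
    """Every shortest s-t path, as tuples of nodes, by explicit enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(v, tail):
        if v == s:
            paths.append(tuple(reversed(tail)))
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                walk(u, tail + [u])

    walk(t, [t])
    return paths


def brute_force_betweenness(network: InteractionNetwork) -> dict[str, float]:
    """BC_i = sum over unordered pairs {j,k} of (paths through i) / (paths)."""
    adj = network.adjacency()
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for j, k in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, j, k)
        if not paths:
            continue
        g = len(paths)
        for v in nodes:
            if v == j or v == k:
                continue
            gi = sum(1 for p in paths if v in p)
            if gi:
                bc[v] += gi / g
    return bc


def random_network(n_nodes: int, p_edge: float, rng: np.random.Generator) -> InteractionNetwork:
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p_edge
    ]
    return InteractionNetwork(edges, genes=nodes)


# ------------------------------------------------------------- fixtures


@pytest.fixture
def path_network() -> InteractionNetwork:
    """A -- B -- C."""
    return InteractionNetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def star_network() -> InteractionNetwork:
    """Hub H with leaves X, Y, Z."""
    return InteractionNetwork([("H", "X"), ("H", "Y"), ("H", "Z")])


@pytest.fixture
def cycle4_network() -> InteractionNetwork:
    """4-cycle A-B-C-D-A."""
    return InteractionNetwork([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
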