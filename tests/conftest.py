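"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the implementation's code paths: the
PageRank oracle is a dense numpy power iteration, path oracles enumerate
simple paths recursively, and the hypergeometric tail is computed from
binomial coefficients.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from kgradiate.graph import EdgeRecord, NodeRecord, PropertyGraph


# ---------------------------------------------------------------------------
# Graph builders


def make_graph(edge_list, labels=None, names=None, extra_nodes=()):
    """Build a PropertyGraph from (u, v) or (u, v, type) tuples."""
    g = PropertyGraph()
    node_ids = set(extra_nodes)
    for e in edge_list:
        node_ids.update(e[:2])
    labels = labels or {}
    names = names or {}
    for nid in sorted(node_ids):
        g.add_node(
            NodeRecord(
                id=nid,
                labels=frozenset(labels.get(nid, {"Entity"})),
                display_name=names.get(nid, nid),
            )
        )
    for e in edge_list:
        etype = e[2] if len(e) > 2 else "input"
        g.add_edge(EdgeRecord(e[0], e[1], etype))
    return g


def random_graph(rng: np.random.Generator, n_nodes: int, p_edge: float) -> PropertyGraph:
    ids = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [
        (u, v)
        for u in ids
        for v in ids
        if u != v and rng.random() < p_edge
    ]
    return make_graph(edges, extra_nodes=ids)


# ---------------------------------------------------------------------------
# Oracles


def dense_ppr_oracle(g: PropertyGraph, sources, damping=0.85, n_iter=5000):
    """Dense power-iteration personalized PageRank.

    Dangling mass goes to the teleport vector; parallel edges add weight.
    """
    order = sorted(g.nodes)
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for e in g.edges:
        A[index[e.source], index[e.target]] += 1.0
    out = A.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            P[i] = A[i] / out[i]
    p = np.zeros(n)
    for s in sources:
        p[index[s]] = 1.0 / len(sources)
    x = p.copy()
    for _ in range(n_iter):
        dangling_mass = x[out == 0].sum()
        x = damping * (x @ P + dangling_mass * p) + (1 - damping) * p
    x = x / x.sum()
    return {nid: x[index[nid]] for nid in order}


def enumerate_simple_paths(adjacency, s, t, max_len=None):
    """All simple s→t paths by recursive enumeration (no networkx)."""
    paths = []

    def walk(node, prefix):
        if max_len is not None and len(prefix) > max_len:
            return
        if node == t:
            paths.append(tuple(prefix))
            return
        for nxt in sorted(adjacency.get(node, ())):
            if nxt not in prefix:
                walk(nxt, prefix + [nxt])

    walk(s, [s])
    return paths


def adjacency_of(g: PropertyGraph):
    adj: dict[str, set[str]] = {}
    for e in g.edges:
        adj.setdefault(e.source, set()).add(e.target)
    return adj


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), from binomial coefficients."""
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


# ---------------------------------------------------------------------------
# Shared fixtures


@pytest.fixture(scope="session")
def default_fixture():
    from kgradiate.fixtures import FixtureSpec, generate_pathway_graph

    spec = FixtureSpec()
    g, manifest = generate_pathway_graph(spec)
    return g, manifest


@pytest.fixture(scope="session")
def processed_view(default_fixture):
    from kgradiate.graph import PreprocessConfig, preprocess_pathway_graph, traversal_view

    g, manifest = default_fixture
    cfg = PreprocessConfig()
    processed = preprocess_pathway_graph(g, cfg)
    view = traversal_view(processed, cfg, exclude_currency=True)
    return view, manifest
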