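"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the code paths they check:
betweenness by explicit shortest-path enumeration, Fisher p by full
hypergeometric enumeration, Mann-Whitney p by permutation enumeration,
and modularity by direct evaluation of the definition over explicit
partitions.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def triangle():
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    return nx.Graph([("HUB", leaf) for leaf in ["L1", "L2", "L3", "L4"]])


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by one bridge edge; modularity optimum 5/14."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )


@pytest.fixture
def two_disjoint_triangles():
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f")]
    )


# ----------------------------------------------------------------- oracles

def betweenness_oracle(g: nx.Graph) -> dict:
    """Traffic by explicit enumeration of all shortest paths per pair."""
    out = {v: 0.0 for v in g.nodes()}
    nodes = sorted(g.nodes())
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins.

    Sums hypergeometric probabilities of every table whose probability is
    <= the observed table's (minimum-likelihood rule), with a small
    relative tolerance on the comparison.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):  # P(a = x) with margins fixed
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def mannwhitney_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Valid for tie-free pooled data; returns (U of x, p).
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(sample_x, sample_y):
        return sum(1.0 for xi in sample_x for yi in sample_y if xi > yi)

    u_obs = u_of(x, y)
    mean_u = n1 * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def modularity_oracle(g: nx.Graph, parts) -> float:
    """Direct evaluation of Q for an explicit list of node sets."""
    m = g.number_of_edges()
    q = 0.0
    for block in parts:
        block = set(block)
        e_c = sum(1 for u, v in g.edges() if u in block and v in block)
        d_c = sum(g.degree(v) for v in block)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def set_partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def random_connected_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """A random connected labelled graph with 3..n_max nodes."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return g
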