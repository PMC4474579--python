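"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from netwfdr import FunctionalNetwork, QuerySet


# ---------------------------------------------------------------- oracles


def stepup_oracle(values, level):
    """Literal step-up definition: largest k with v_(k) <= k*level/m.

    Returns the set of rejected input indices.  Independent of the
    vectorised implementation (pure-python loop over candidate k).
    """
    m = len(values)
    order = sorted(range(m), key=lambda i: (values[i], i))
    k_star = 0
    for k in range(m, 0, -1):
        if values[order[k - 1]] <= k * level / m:
            k_star = k
            break
    return set(order[:k_star])


def hypergeom_tail_oracle(k, n, K, N):
    """Exact upper-tail P(X >= k) by rational pmf summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def trc_oracle(net: FunctionalNetwork, universe):
    """Per-gene incident-confidence sum by a full scan of the edge list."""
    totals = {g: 0.0 for g in universe}
    for a, b, c in net.edges():
        if a in totals:
            totals[a] += c
        if b in totals:
            totals[b] += c
    return totals


def bfs_subnet_oracle(net: FunctionalNetwork, seeds, min_confidence, max_hops):
    """Brute-force breadth-first reachability over the thresholded graph."""
    layer = {s for s in seeds if s in net.graph}
    seen = set(layer)
    for _ in range(int(max_hops)):
        nxt = set()
        for u in layer:
            for v in net.graph[u]:
                if net.confidence(u, v) > min_confidence and v not in seen:
                    nxt.add(v)
        seen |= nxt
        layer = nxt
        if not layer:
            break
    return seen


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def star_net() -> FunctionalNetwork:
    """q--a(0.5), q--b(0.2), a--c(0.4): the hop/threshold worked example."""
    return FunctionalNetwork.from_edges(
        [("q", "a", 0.5), ("q", "b", 0.2), ("a", "c", 0.4)]
    )


@pytest.fixture
def queries_q() -> QuerySet:
    return QuerySet.from_iterable(["q"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150617)


def random_network(rng: np.random.Generator, n_nodes: int = 10, n_edges: int = 15):
    """Random multigraph-free weighted network for oracle comparisons."""
    genes = [f"n{i}" for i in range(n_nodes)]
    triples = []
    for _ in range(n_edges):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        triples.append((genes[a], genes[b], float(rng.uniform(0.01, 1.0))))
    return FunctionalNetwork.from_edges(triples), genes
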