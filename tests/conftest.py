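"""Shared fixtures: random graph/attribute factories and brute-force
two-path oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ergmee import AttributeSet, DirectedGraph


def random_graph(rng: np.random.Generator, n: int,
                 density: float = 0.25) -> DirectedGraph:
    g = DirectedGraph(n)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < density:
                g.add_arc(i, j)
    return g


def random_attrs(rng: np.random.Generator, n: int,
                 missing: float = 0.1) -> AttributeSet:
    attrs = AttributeSet.empty(n)
    b = rng.integers(0, 2, size=n).astype(float)
    b[rng.random(n) < missing] = np.nan
    attrs.add_binary("b", b)
    c = rng.integers(0, 3, size=n)
    c[rng.random(n) < missing] = -1
    attrs.add_categorical("c", c)
    u = rng.normal(size=n)
    u[rng.random(n) < missing] = np.nan
    attrs.add_continuous("u", u)
    return attrs


def brute_two_path_tables(g: DirectedGraph):
    """O(N^3) recomputation of mix2 / in2 / out2 from scratch."""
    n = g.n_nodes
    mix2, in2, out2 = {}, {}, {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = sum(1 for h in range(n) if h != i and h != j
                    and g.has_arc(i, h) and g.has_arc(h, j))
            if m:
                mix2[(i, j)] = m
            if i < j:
                d = sum(1 for h in range(n) if h != i and h != j
                        and g.has_arc(h, i) and g.has_arc(h, j))
                if d:
                    in2[(i, j)] = d
                u = sum(1 for h in range(n) if h != i and h != j
                        and g.has_arc(i, h) and g.has_arc(j, h))
                if u:
                    out2[(i, j)] = u
    return mix2, in2, out2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
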