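"""Mutable sparse directed graph with incrementally maintained two-path tables.

The graph keeps, besides the usual out/in adjacency lists and a flat arc
list, three hash tables of two-path counts keyed by node pairs:

* ``mix2[(i, j)]``  -- number of directed two-paths i -> h -> j (ordered key),
* ``in2[{i, j}]``   -- number of common predecessors h with h -> i and h -> j,
* ``out2[{i, j}]``  -- number of common successors h with i -> h and j -> h.

The symmetric tables are keyed on sorted pairs.  Entries whose count falls
to zero are deleted, so table size is bounded by the number of node pairs
with a nonzero count.  Arc insertion and deletion update all three tables
in O(deg(i) + deg(j)) by scanning the endpoints' neighbourhoods, which is
what makes change-statistic computation O(local) during MCMC sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DirectedGraph", "AttributeSet"]


class DirectedGraph:
    """Sparse mutable digraph on a fixed node set {0, ..., n_nodes-1}.

    No self-loops, no duplicate arcs.  Arc deletion compacts the flat arc
    list by swap-with-last, so arc order is not preserved (uniform random
    arc selection is unaffected).
    """

    __slots__ = ("n_nodes", "out_adj", "in_adj", "arc_list", "_arc_pos",
                 "mix2", "in2", "out2")

    def __init__(self, n_nodes: int):
        if n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        self.n_nodes = int(n_nodes)
        self.out_adj: list[list[int]] = [[] for _ in range(n_nodes)]
        self.in_adj: list[list[int]] = [[] for _ in range(n_nodes)]
        self.arc_list: list[tuple[int, int]] = []
        self._arc_pos: dict[tuple[int, int], int] = {}
        self.mix2: dict[tuple[int, int], int] = {}
        self.in2: dict[tuple[int, int], int] = {}
        self.out2: dict[tuple[int, int], int] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_arcs(cls, n_nodes: int, arcs) -> "DirectedGraph":
        g = cls(n_nodes)
        for i, j in arcs:
            g.add_arc(int(i), int(j))
        return g

    def copy(self) -> "DirectedGraph":
        g = DirectedGraph.__new__(DirectedGraph)
        g.n_nodes = self.n_nodes
        g.out_adj = [list(a) for a in self.out_adj]
        g.in_adj = [list(a) for a in self.in_adj]
        g.arc_list = list(self.arc_list)
        g._arc_pos = dict(self._arc_pos)
        g.mix2 = dict(self.mix2)
        g.in2 = dict(self.in2)
        g.out2 = dict(self.out2)
        return g

    # -- queries ------------------------------------------------------

    @property
    def n_arcs(self) -> int:
        return len(self.arc_list)

    def has_arc(self, i: int, j: int) -> bool:
        return (i, j) in self._arc_pos

    def degrees(self, i: int) -> tuple[int, int]:
        """(in-degree, out-degree) of node i."""
        if not 0 <= i < self.n_nodes:
            raise ValueError(f"node id {i} out of range")
        return len(self.in_adj[i]), len(self.out_adj[i])

    def density(self) -> float:
        n = self.n_nodes
        return self.n_arcs / (n * (n - 1)) if n > 1 else 0.0

    def mix2_count(self, i: int, j: int) -> int:
        return self.mix2.get((i, j), 0)

    def in2_count(self, i: int, j: int) -> int:
        return self.in2.get((i, j) if i < j else (j, i), 0)

    def out2_count(self, i: int, j: int) -> int:
        return self.out2.get((i, j) if i < j else (j, i), 0)

    # -- mutation -----------------------------------------------------

    def _check_ids(self, i: int, j: int) -> None:
        n = self.n_nodes
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"arc ({i}, {j}) out of range for n={n}")
        if i == j:
            raise ValueError(f"self-loop ({i}, {i}) not allowed")

    def add_arc(self, i: int, j: int) -> None:
        self._check_ids(i, j)
        if (i, j) in self._arc_pos:
            raise ValueError(f"duplicate arc ({i}, {j})")
        # scan neighbourhoods before inserting so the new arc never pairs
        # with itself; diagonal two-path entries (i,i) are never stored
        mix2, in2, out2 = self.mix2, self.in2, self.out2
        for h in self.out_adj[j]:          # new two-path i -> j -> h
            if h != i:
                _inc(mix2, (i, h), 1)
        for h in self.in_adj[i]:           # new two-path h -> i -> j
            if h != j:
                _inc(mix2, (h, j), 1)
        for h in self.out_adj[i]:          # i is now a common predecessor of j, h
            _inc(in2, (j, h) if j < h else (h, j), 1)
        for h in self.in_adj[j]:           # j is now a common successor of i, h
            _inc(out2, (i, h) if i < h else (h, i), 1)
        self._arc_pos[(i, j)] = len(self.arc_list)
        self.arc_list.append((i, j))
        self.out_adj[i].append(j)
        self.in_adj[j].append(i)

    def delete_arc(self, i: int, j: int) -> None:
        self._check_ids(i, j)
        pos = self._arc_pos.pop((i, j), None)
        if pos is None:
            raise ValueError(f"arc ({i}, {j}) not present")
        last = self.arc_list.pop()
        if pos < len(self.arc_list):
            self.arc_list[pos] = last
            self._arc_pos[last] = pos
        self.out_adj[i].remove(j)
        self.in_adj[j].remove(i)
        # scans after removal mirror add_arc's scans before insertion
        mix2, in2, out2 = self.mix2, self.in2, self.out2
        for h in self.out_adj[j]:
            if h != i:
                _inc(mix2, (i, h), -1)
        for h in self.in_adj[i]:
            if h != j:
                _inc(mix2, (h, j), -1)
        for h in self.out_adj[i]:
            _inc(in2, (j, h) if j < h else (h, j), -1)
        for h in self.in_adj[j]:
            _inc(out2, (i, h) if i < h else (h, i), -1)

    # -- random selection ---------------------------------------------

    def random_dyad(self, rng: np.random.Generator) -> tuple[int, int]:
        """Uniform ordered pair (i, j), i != j."""
        n = self.n_nodes
        if n < 2:
            raise ValueError("need at least 2 nodes to draw a dyad")
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        return i, j

    def random_arc(self, rng: np.random.Generator) -> tuple[int, int]:
        """Uniform existing arc, O(1) via the flat arc list."""
        if not self.arc_list:
            raise ValueError("graph has no arcs")
        return self.arc_list[int(rng.integers(len(self.arc_list)))]

    # -- misc ----------------------------------------------------------

    def arcs_array(self) -> np.ndarray:
        """(n_arcs, 2) int64 array of (tail, head) pairs."""
        if not self.arc_list:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(self.arc_list, dtype=np.int64)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DirectedGraph(n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"


def _inc(table: dict, key, delta: int) -> None:
    c = table.get(key, 0) + delta
    if c == 0:
        if key in table:
            del table[key]
    elif c < 0:
        raise AssertionError(f"two-path count for {key} went negative")
    else:
        table[key] = c


@dataclass
class AttributeSet:
    """Typed node attribute columns.

    binary      -- float64 vectors of {0.0, 1.0, nan}; nan marks missing
    categorical -- int64 vectors of dense codes >= 0; -1 marks missing
    continuous  -- float64 vectors; nan marks missing

    Any statistic term that touches a missing value contributes 0.
    """

    n_nodes: int
    binary: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: dict[str, np.ndarray] = field(default_factory=dict)
    continuous: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def empty(cls, n_nodes: int) -> "AttributeSet":
        return cls(n_nodes=n_nodes)

    def add_binary(self, name: str, values) -> None:
        v = np.asarray(values, dtype=np.float64)
        self._check(name, v)
        ok = np.isnan(v) | (v == 0.0) | (v == 1.0)
        if not ok.all():
            raise ValueError(f"binary attribute {name!r} has non-0/1 values")
        self.binary[name] = v

    def add_categorical(self, name: str, values) -> None:
        v = np.asarray(values, dtype=np.int64)
        self._check(name, v)
        if (v < -1).any():
            raise ValueError(f"categorical attribute {name!r} has codes < -1")
        self.categorical[name] = v

    def add_continuous(self, name: str, values) -> None:
        v = np.asarray(values, dtype=np.float64)
        self._check(name, v)
        self.continuous[name] = v

    def _check(self, name: str, v: np.ndarray) -> None:
        if v.shape != (self.n_nodes,):
            raise ValueError(
                f"attribute {name!r} has length {v.shape}, expected ({self.n_nodes},)")
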