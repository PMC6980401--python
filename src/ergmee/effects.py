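"""ERGM effects for directed networks: full statistics and change statistics.

Every effect has two faces:

* :func:`full_stat` evaluates the statistic directly from its defining sum,
  in up to O(N^3) time.  This is the reference definition, used as a test
  oracle and for descriptive output; samplers never call it.
* :func:`change_stat` evaluates the difference in the statistic caused by
  toggling one arc, using only the endpoints' neighbourhoods and the
  incrementally maintained two-path tables (O(local) time).

Structural effects cover density (Arc), mutuality (Reciprocity), degree
spread (alternating k-in/out-stars AinS/AoutS with geometric damping
``lambda``), transitive and cyclic closure (AT-T, AT-C), popularity and
activity closure (AKT-D, AKT-U), multiple connectivity and shared
popularity/activity (A2P-T, A2P-D, A2P-U and the combined A2P-TD), and an
isolate count.  Attribute effects cover binary sender/receiver/interaction,
categorical (mis)matching with reciprocity variants, and continuous
sender/receiver/absolute-difference homophily.

Conventions: reciprocity-style statistics count each mutual dyad once.
A2P-TD is defined as z_A2P-T + z_A2P-D / 2.  Terms touching a missing
attribute value contribute zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph import AttributeSet, DirectedGraph

__all__ = [
    "EffectSpec", "ModelSpec", "full_stat", "change_stat", "stat_vector",
    "EFFECT_NAMES", "ALTERNATING_EFFECTS", "ATTR_KIND", "EFFECT_CODES",
]

# canonical order; integer codes index into the compiled kernels
EFFECT_NAMES = (
    "Arc", "Reciprocity", "AinS", "AoutS", "AT-T", "AT-C", "AKT-D", "AKT-U",
    "A2P-T", "A2P-D", "A2P-TD", "A2P-U", "Isolates",
    "Sender", "Receiver", "Interaction",
    "Matching", "Mismatching", "MatchingReciprocity", "MismatchingReciprocity",
    "ContinuousSender", "ContinuousReceiver", "Diff",
)
EFFECT_CODES = {name: k for k, name in enumerate(EFFECT_NAMES)}

ALTERNATING_EFFECTS = frozenset(
    {"AinS", "AoutS", "AT-T", "AT-C", "AKT-D", "AKT-U",
     "A2P-T", "A2P-D", "A2P-TD", "A2P-U"})

# attribute kind required by each attribute effect
ATTR_KIND = {
    "Sender": "binary", "Receiver": "binary", "Interaction": "binary",
    "Matching": "categorical", "Mismatching": "categorical",
    "MatchingReciprocity": "categorical", "MismatchingReciprocity": "categorical",
    "ContinuousSender": "continuous", "ContinuousReceiver": "continuous",
    "Diff": "continuous",
}


@dataclass(frozen=True)
class EffectSpec:
    """One model effect: a named statistic, optionally bound to a damping
    parameter ``lam`` (alternating effects) and/or an attribute column."""

    name: str
    lam: Optional[float] = None
    attr: Optional[str] = None

    def __post_init__(self):
        if self.name not in EFFECT_CODES:
            raise ValueError(f"unknown effect {self.name!r}")
        if self.name in ALTERNATING_EFFECTS:
            lam = 2.0 if self.lam is None else float(self.lam)
            if lam < 1.0:
                raise ValueError(f"{self.name}: lambda must be >= 1, got {lam}")
            object.__setattr__(self, "lam", lam)
        elif self.lam is not None:
            raise ValueError(f"{self.name} takes no lambda")
        if self.name in ATTR_KIND:
            if self.attr is None:
                raise ValueError(f"{self.name} requires an attribute name")
        elif self.attr is not None:
            raise ValueError(f"{self.name} takes no attribute")

    @property
    def code(self) -> int:
        return EFFECT_CODES[self.name]

    @property
    def label(self) -> str:
        return self.name if self.attr is None else f"{self.name}({self.attr})"


class ModelSpec:
    """Ordered list of effects; Arc (the density intercept) must come first."""

    def __init__(self, effects):
        effects = [e if isinstance(e, EffectSpec) else EffectSpec(e)
                   for e in effects]
        if not effects or effects[0].name != "Arc":
            raise ValueError("the Arc effect must be included first")
        labels = [e.label for e in effects]
        if len(set(labels)) != len(labels):
            raise ValueError("effect names must be unique within a model")
        self.effects: list[EffectSpec] = effects

    def __len__(self) -> int:
        return len(self.effects)

    def __iter__(self):
        return iter(self.effects)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.effects]

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModelSpec({self.labels})"


# ---------------------------------------------------------------------------
# full statistics (reference definitions; O(N^3) acceptable)
# ---------------------------------------------------------------------------

def _l2(g: DirectedGraph, i: int, j: int) -> int:
    """Number of directed two-paths i -> h -> j, by brute force."""
    return sum(1 for h in range(g.n_nodes)
               if h != i and h != j and g.has_arc(i, h) and g.has_arc(h, j))


def _l2d(g: DirectedGraph, i: int, j: int) -> int:
    """Common predecessors: h -> i and h -> j."""
    return sum(1 for h in range(g.n_nodes)
               if h != i and h != j and g.has_arc(h, i) and g.has_arc(h, j))


def _l2u(g: DirectedGraph, i: int, j: int) -> int:
    """Common successors: i -> h and j -> h."""
    return sum(1 for h in range(g.n_nodes)
               if h != i and h != j and g.has_arc(i, h) and g.has_arc(j, h))


def _alt_star(degrees, lam: float) -> float:
    """sum_{k>=2} (-1)^k S_k / lam^(k-2) with S_k = sum_i C(d_i, k)."""
    total = 0.0
    for d in degrees:
        for k in range(2, d + 1):
            total += (-1) ** k * math.comb(d, k) / lam ** (k - 2)
    return total


def _geom(lam: float, count: int) -> float:
    return 1.0 - (1.0 - 1.0 / lam) ** count


def _attr_vec(attrs: AttributeSet, effect: EffectSpec) -> np.ndarray:
    kind = ATTR_KIND[effect.name]
    table = getattr(attrs, kind)
    if effect.attr not in table:
        raise KeyError(
            f"{effect.name} needs {kind} attribute {effect.attr!r}, "
            f"available: {sorted(table)}")
    return table[effect.attr]


def full_stat(effect: EffectSpec, g: DirectedGraph,
              attrs: Optional[AttributeSet] = None) -> float:
    """Evaluate one statistic directly from its defining sum."""
    name, lam = effect.name, effect.lam
    n = g.n_nodes

    if name == "Arc":
        return float(g.n_arcs)
    if name == "Reciprocity":
        return float(sum(1 for (i, j) in g.arc_list if i < j and g.has_arc(j, i)))
    if name == "AoutS":
        return _alt_star([len(a) for a in g.out_adj], lam)
    if name == "AinS":
        return _alt_star([len(a) for a in g.in_adj], lam)
    if name == "AT-T":
        return lam * sum(_geom(lam, _l2(g, i, j)) for (i, j) in g.arc_list)
    if name == "AT-C":
        return lam * sum(_geom(lam, _l2(g, j, i)) for (i, j) in g.arc_list)
    if name == "AKT-D":
        return lam * sum(_geom(lam, _l2d(g, i, j)) for (i, j) in g.arc_list)
    if name == "AKT-U":
        return lam * sum(_geom(lam, _l2u(g, i, j)) for (i, j) in g.arc_list)
    if name == "A2P-T":
        return lam * sum(_geom(lam, _l2(g, i, j))
                         for i in range(n) for j in range(i + 1, n))
    if name == "A2P-D":
        return lam * sum(_geom(lam, _l2d(g, i, j))
                         for i in range(n) for j in range(i + 1, n))
    if name == "A2P-U":
        return lam * sum(_geom(lam, _l2u(g, i, j))
                         for i in range(n) for j in range(i + 1, n))
    if name == "A2P-TD":
        t = EffectSpec("A2P-T", lam=lam)
        d = EffectSpec("A2P-D", lam=lam)
        return full_stat(t, g) + full_stat(d, g) / 2.0
    if name == "Isolates":
        return float(sum(1 for v in range(n)
                         if not g.out_adj[v] and not g.in_adj[v]))

    if attrs is None:
        raise ValueError(f"{name} requires node attributes")
    a = _attr_vec(attrs, effect)

    if name == "Sender":
        return float(sum(a[i] for (i, j) in g.arc_list if not np.isnan(a[i])))
    if name == "Receiver":
        return float(sum(a[j] for (i, j) in g.arc_list if not np.isnan(a[j])))
    if name == "Interaction":
        return float(sum(a[i] * a[j] for (i, j) in g.arc_list
                         if not (np.isnan(a[i]) or np.isnan(a[j]))))
    if name == "ContinuousSender":
        return float(sum(a[i] for (i, j) in g.arc_list if not np.isnan(a[i])))
    if name == "ContinuousReceiver":
        return float(sum(a[j] for (i, j) in g.arc_list if not np.isnan(a[j])))
    if name == "Diff":
        return float(sum(abs(a[i] - a[j]) for (i, j) in g.arc_list
                         if not (np.isnan(a[i]) or np.isnan(a[j]))))

    def match(i, j):
        if a[i] < 0 or a[j] < 0:
            return None
        return bool(a[i] == a[j])

    if name == "Matching":
        return float(sum(1 for (i, j) in g.arc_list if match(i, j) is True))
    if name == "Mismatching":
        return float(sum(1 for (i, j) in g.arc_list if match(i, j) is False))
    if name == "MatchingReciprocity":
        return float(sum(1 for (i, j) in g.arc_list
                         if i < j and g.has_arc(j, i) and match(i, j) is True))
    if name == "MismatchingReciprocity":
        return float(sum(1 for (i, j) in g.arc_list
                         if i < j and g.has_arc(j, i) and match(i, j) is False))

    raise AssertionError(f"unhandled effect {name}")  # pragma: no cover


def stat_vector(model: ModelSpec, g: DirectedGraph,
                attrs: Optional[AttributeSet] = None) -> np.ndarray:
    return np.array([full_stat(e, g, attrs) for e in model], dtype=np.float64)


# ---------------------------------------------------------------------------
# change statistics (O(local); use adjacency and the two-path tables only)
# ---------------------------------------------------------------------------

def _change_add(effect: EffectSpec, g: DirectedGraph,
                attrs: Optional[AttributeSet], i: int, j: int) -> float:
    """delta z for adding arc (i, j); the arc must be absent from g."""
    name, lam = effect.name, effect.lam

    if name == "Arc":
        return 1.0
    if name == "Reciprocity":
        return 1.0 if g.has_arc(j, i) else 0.0
    if name == "AoutS":
        return lam * _geom(lam, len(g.out_adj[i]))
    if name == "AinS":
        return lam * _geom(lam, len(g.in_adj[j]))

    r = 1.0 - 1.0 / lam if lam is not None else None

    if name == "AT-T":
        delta = lam * _geom(lam, g.mix2_count(i, j))
        for h in g.out_adj[j]:          # new two-path i -> j -> h
            if h != i and g.has_arc(i, h):
                delta += r ** g.mix2_count(i, h)
        for h in g.in_adj[i]:           # new two-path h -> i -> j
            if h != j and g.has_arc(h, j):
                delta += r ** g.mix2_count(h, j)
        return delta
    if name == "AT-C":
        delta = lam * _geom(lam, g.mix2_count(j, i))
        for h in g.out_adj[j]:
            if h != i and g.has_arc(h, i):
                delta += r ** g.mix2_count(i, h)
        for h in g.in_adj[i]:
            if h != j and g.has_arc(j, h):
                delta += r ** g.mix2_count(h, j)
        return delta
    if name == "AKT-D":
        delta = lam * _geom(lam, g.in2_count(i, j))
        for h in g.out_adj[i]:          # i becomes a common predecessor of {j, h}
            if h != j:
                w = (1 if g.has_arc(j, h) else 0) + (1 if g.has_arc(h, j) else 0)
                if w:
                    delta += w * r ** g.in2_count(j, h)
        return delta
    if name == "AKT-U":
        delta = lam * _geom(lam, g.out2_count(i, j))
        for h in g.in_adj[j]:           # j becomes a common successor of {i, h}
            if h != i:
                w = (1 if g.has_arc(i, h) else 0) + (1 if g.has_arc(h, i) else 0)
                if w:
                    delta += w * r ** g.out2_count(i, h)
        return delta
    if name == "A2P-T":
        delta = 0.0
        for h in g.out_adj[j]:
            if h != i and i < h:
                delta += r ** g.mix2_count(i, h)
        for h in g.in_adj[i]:
            if h != j and h < j:
                delta += r ** g.mix2_count(h, j)
        return delta
    if name == "A2P-D":
        delta = 0.0
        for h in g.out_adj[i]:
            if h != j:
                delta += r ** g.in2_count(j, h)
        return delta
    if name == "A2P-U":
        delta = 0.0
        for h in g.in_adj[j]:
            if h != i:
                delta += r ** g.out2_count(i, h)
        return delta
    if name == "A2P-TD":
        t = EffectSpec("A2P-T", lam=lam)
        d = EffectSpec("A2P-D", lam=lam)
        return _change_add(t, g, attrs, i, j) + _change_add(d, g, attrs, i, j) / 2.0
    if name == "Isolates":
        di_in, di_out = len(g.in_adj[i]), len(g.out_adj[i])
        dj_in, dj_out = len(g.in_adj[j]), len(g.out_adj[j])
        return -float(di_in + di_out == 0) - float(dj_in + dj_out == 0)

    if attrs is None:
        raise ValueError(f"{name} requires node attributes")
    a = _attr_vec(attrs, effect)

    if name == "Sender" or name == "ContinuousSender":
        return 0.0 if np.isnan(a[i]) else float(a[i])
    if name == "Receiver" or name == "ContinuousReceiver":
        return 0.0 if np.isnan(a[j]) else float(a[j])
    if name == "Interaction":
        if np.isnan(a[i]) or np.isnan(a[j]):
            return 0.0
        return float(a[i] * a[j])
    if name == "Diff":
        if np.isnan(a[i]) or np.isnan(a[j]):
            return 0.0
        return float(abs(a[i] - a[j]))

    if a[i] < 0 or a[j] < 0:
        return 0.0
    same = bool(a[i] == a[j])
    if name == "Matching":
        return 1.0 if same else 0.0
    if name == "Mismatching":
        return 0.0 if same else 1.0
    if name == "MatchingReciprocity":
        return 1.0 if (same and g.has_arc(j, i)) else 0.0
    if name == "MismatchingReciprocity":
        return 1.0 if (not same and g.has_arc(j, i)) else 0.0

    raise AssertionError(f"unhandled effect {name}")  # pragma: no cover


def change_stat(effect: EffectSpec, g: DirectedGraph,
                attrs: Optional[AttributeSet], i: int, j: int,
                is_add: bool) -> float:
    """Change in the statistic caused by toggling arc (i, j).

    For an addition (arc absent) this is z(x + arc) - z(x); for a deletion
    (arc present) it is z(x - arc) - z(x), computed as the negative of the
    addition value on the post-deletion graph.  Deletion temporarily
    removes the arc and restores it; the flat arc list may be permuted.
    """
    if is_add:
        if g.has_arc(i, j):
            raise ValueError(f"arc ({i}, {j}) already present")
        return _change_add(effect, g, attrs, i, j)
    if not g.has_arc(i, j):
        raise ValueError(f"arc ({i}, {j}) not present")
    g.delete_arc(i, j)
    try:
        return -_change_add(effect, g, attrs, i, j)
    finally:
        g.add_arc(i, j)


def change_vector(model: ModelSpec, g: DirectedGraph,
                  attrs: Optional[AttributeSet], i: int, j: int,
                  is_add: bool) -> np.ndarray:
    """Signed change-statistic vector for toggling arc (i, j)."""
    if is_add:
        return np.array([_change_add(e, g, attrs, i, j) for e in model])
    if not g.has_arc(i, j):
        raise ValueError(f"arc ({i}, {j}) not present")
    g.delete_arc(i, j)
    try:
        return -np.array([_change_add(e, g, attrs, i, j) for e in model])
    finally:
        g.add_arc(i, j)
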