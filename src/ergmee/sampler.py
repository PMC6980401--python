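"""Metropolis-Hastings ERGM samplers for directed networks.

Two proposal schemes are provided:

* the **basic** sampler toggles a uniformly chosen ordered dyad, accepting
  with probability ``min(1, exp(sum_A theta_A * delta_z_A))``;
* the **improved fixed density (IFD)** sampler alternates arc insertions
  (uniform absent dyad) and deletions (uniform existing arc) with an
  auxiliary parameter ``v`` entering the acceptance probability with
  opposite signs for the two move types, so that the simulated networks
  keep the observed number of arcs.  ``v`` is adapted during burn-in so
  insertion and deletion acceptance rates balance, and frozen afterwards.

:func:`basic_step` and :func:`ifd_step` are the transparent pure-Python
reference steps operating on :class:`~ergmee.graph.DirectedGraph`;
:func:`simulate` and the estimator drive the compiled kernels in
:mod:`ergmee._core`, which implement the same proposals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _core
from .graph import AttributeSet, DirectedGraph
from .effects import ModelSpec, change_vector

__all__ = ["SamplerState", "SamplerConfig", "basic_step", "ifd_step", "simulate"]


@dataclass
class SamplerConfig:
    mode: str = "basic"                 # "basic" | "ifd"
    steps_per_block: int = 1000
    ifd_adapt_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("basic", "ifd"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.steps_per_block < 1:
            raise ValueError("steps_per_block must be >= 1")


@dataclass
class SamplerState:
    """Chain state: current graph, running statistic divergence
    ``dz = z(x_t) - z(x_obs)``, IFD auxiliary parameter and counters."""

    graph: DirectedGraph
    dz: np.ndarray
    rng: np.random.Generator
    ifd_v: float = 0.0
    observed_arcs: int = 0              # L0, the fixed density target
    accept_count: int = 0
    proposal_count: int = 0

    @classmethod
    def from_observed(cls, g_obs: DirectedGraph, n_effects: int,
                      seed: int = 0) -> "SamplerState":
        return cls(graph=g_obs.copy(), dz=np.zeros(n_effects),
                   rng=np.random.default_rng(seed),
                   observed_arcs=g_obs.n_arcs)


def _accept(state: SamplerState, lp: float) -> bool:
    return lp >= 0.0 or state.rng.random() < np.exp(lp)


def basic_step(state: SamplerState, model: ModelSpec, theta: np.ndarray,
               attrs: Optional[AttributeSet] = None) -> SamplerState:
    """One uniform-dyad toggle proposal (in place); returns the state."""
    g = state.graph
    i, j = g.random_dyad(state.rng)
    is_add = not g.has_arc(i, j)
    delta = change_vector(model, g, attrs, i, j, is_add)
    state.proposal_count += 1
    if _accept(state, float(np.dot(theta, delta))):
        if is_add:
            g.add_arc(i, j)
        else:
            g.delete_arc(i, j)
        state.dz += delta
        state.accept_count += 1
    return state


def ifd_step(state: SamplerState, model: ModelSpec, theta: np.ndarray,
             attrs: Optional[AttributeSet] = None,
             adapt_rate: float = 0.0) -> SamplerState:
    """One IFD proposal (in place).

    The move type is determined by the current arc count relative to the
    observed count L0: an insertion at L0, a deletion at L0+1, so the
    count never leaves {L0, L0+1}.  With ``adapt_rate > 0`` the auxiliary
    parameter is adapted toward balanced insertion/deletion acceptance.
    """
    g = state.graph
    L0 = state.observed_arcs
    if g.n_arcs <= L0:
        if g.n_arcs == g.n_nodes * (g.n_nodes - 1):
            raise ValueError("IFD insertion impossible: graph is complete")
        while True:
            i, j = g.random_dyad(state.rng)
            if not g.has_arc(i, j):
                break
        delta = change_vector(model, g, attrs, i, j, True)
        accepted = _accept(state, float(np.dot(theta, delta)) + state.ifd_v)
        if accepted:
            g.add_arc(i, j)
            state.dz += delta
        if adapt_rate:
            state.ifd_v += -adapt_rate if accepted else adapt_rate
    else:
        if g.n_arcs == 0:
            raise ValueError("IFD deletion impossible: graph is empty")
        i, j = g.random_arc(state.rng)
        delta = change_vector(model, g, attrs, i, j, False)
        accepted = _accept(state, float(np.dot(theta, delta)) - state.ifd_v)
        if accepted:
            g.delete_arc(i, j)
            state.dz += delta
        if adapt_rate:
            state.ifd_v += adapt_rate if accepted else -adapt_rate
    state.proposal_count += 1
    state.accept_count += int(accepted)
    return state


def simulate(model: ModelSpec, theta, n_nodes: int,
             attrs: Optional[AttributeSet] = None,
             burn_in: int = 10_000_000, sample_gap: int = 1_000_000,
             n_samples: int = 1, seed: int = 0,
             start: Optional[DirectedGraph] = None,
             arc_capacity: Optional[int] = None) -> list[DirectedGraph]:
    """Draw networks from the ERGM distribution with the basic sampler.

    The chain starts from the empty graph (or ``start``), runs ``burn_in``
    proposals, then takes a snapshot every ``sample_gap`` proposals until
    ``n_samples`` graphs are collected.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if len(theta) != len(model):
        raise ValueError("theta length must match the number of effects")
    if burn_in < 0 or sample_gap < 0:
        raise ValueError("burn_in and sample_gap must be >= 0")
    if start is not None and start.n_nodes != n_nodes:
        raise ValueError("start graph has wrong number of nodes")
    arcs = start.arcs_array() if start is not None else None
    if arc_capacity is None and start is None:
        # ab-initio chains on large sparse models stay sparse; small graphs
        # get the full dyad space
        arc_capacity = _core.default_capacity(n_nodes, 0)
    st = _core.build_state(n_nodes, arcs, arc_capacity)
    mdl = _core.encode_model(model, attrs, n_nodes)
    dz = np.zeros(len(model))
    _core.seed_rng(seed)
    _core._run_basic(st, mdl, theta, dz, burn_in)
    samples = [_core.state_to_graph(st)]
    for _ in range(n_samples - 1):
        _core._run_basic(st, mdl, theta, dz, sample_gap)
        samples.append(_core.state_to_graph(st))
    return samples
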