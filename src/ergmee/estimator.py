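"""Equilibrium-expectation (EE) parameter estimation with contrastive-
divergence initialization.

EE starts a Metropolis-Hastings chain *at the observed network*, runs a
short burst of proposals, then nudges every parameter against the sign of
the accumulated statistic divergence dz_A = z_A(x_t) - z_A(x_obs):

    delta theta_A = -sign(dz_A) * a * max(|theta_A|, theta_min)

exploiting the exponential-family property that the expected value of a
statistic is monotonically increasing in its parameter.  After enough
updates each divergence oscillates around zero and the parameter
oscillates around the MLE; the point estimate is the mean of the second
half of the parameter trace.  A simplified additive rule
(delta theta_A = -a * dz_A) is available as ``update_rule="simple"``.

Initial values come from short-run contrastive divergence (CD): the same
update applied to divergences accumulated over short chains that are
*reset to the observed network* before every update.

Multiple independent runs (distinct seeds, deterministic order) are
pooled downstream by inverse-variance weighting (:mod:`ergmee.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _core, inference
from .graph import AttributeSet, DirectedGraph
from .effects import ModelSpec

__all__ = ["EEConfig", "EERunResult", "InitializationError",
           "cd_init", "ee_estimate", "run_parallel"]


class InitializationError(RuntimeError):
    """Contrastive-divergence initialization produced non-finite values."""


@dataclass
class EEConfig:
    """Algorithm constants for CD initialization and the EE loop.

    ``ee_steps`` outer iterations, each of ``steps_per_update`` sampler
    proposals followed by one parameter update.  ``learning_rate`` and
    ``theta_min`` parameterize the multiplicative signed update;
    ``cd_learning_rate`` is the (coarser) rate used during initialization.
    """

    ee_steps: int = 1000
    steps_per_update: int = 1000
    cd_steps: int = 500
    cd_updates: int = 200
    learning_rate: float = 0.01
    cd_learning_rate: float = 0.1
    theta_min: float = 0.01
    sampler_mode: str = "basic"          # "basic" | "ifd"
    update_rule: str = "multiplicative"  # "multiplicative" | "simple"
    ifd_adapt_rate: float = 0.01
    n_runs: int = 8
    seed: int = 0
    arc_capacity: Optional[int] = None

    def __post_init__(self):
        for name in ("ee_steps", "steps_per_update", "cd_steps",
                     "cd_updates", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("learning_rate", "cd_learning_rate", "theta_min",
                     "ifd_adapt_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampler_mode not in ("basic", "ifd"):
            raise ValueError(f"unknown sampler_mode {self.sampler_mode!r}")
        if self.update_rule not in ("multiplicative", "simple"):
            raise ValueError(f"unknown update_rule {self.update_rule!r}")


@dataclass
class EERunResult:
    """One independent estimation run."""

    theta_trace: np.ndarray              # (updates, effects)
    dz_trace: np.ndarray                 # (updates, effects)
    theta_hat: np.ndarray
    se: np.ndarray
    converged: bool
    t_ratios: np.ndarray
    ifd_v: float = 0.0
    accept_rate: float = 0.0
    singular: bool = False


def _update_theta(theta: np.ndarray, dz: np.ndarray, rate: float,
                  theta_min: float, rule: str) -> np.ndarray:
    if rule == "simple":
        return theta - rate * dz
    step = rate * np.maximum(np.abs(theta), theta_min)
    return theta - np.sign(dz) * step


def cd_init(g_obs: DirectedGraph, model: ModelSpec,
            attrs: Optional[AttributeSet], cfg: EEConfig,
            seed: Optional[int] = None) -> np.ndarray:
    """Contrastive-divergence initial parameter values.

    Runs ``cd_updates`` short chains of ``cd_steps`` proposals, each
    restarted from the observed network, applying the signed update after
    each chain.  Starts from theta = 0.
    """
    return _cd_init_full(g_obs, model, attrs, cfg, seed)[0]


def _cd_init_full(g_obs: DirectedGraph, model: ModelSpec,
                  attrs: Optional[AttributeSet], cfg: EEConfig,
                  seed: Optional[int] = None) -> tuple[np.ndarray, float]:
    """CD initialization returning (theta0, adapted IFD auxiliary v)."""
    if g_obs.n_arcs == 0:
        raise ValueError("observed graph must have at least one arc")
    if seed is None:
        seed = cfg.seed
    arcs0 = g_obs.arcs_array()
    cap = cfg.arc_capacity or _core.default_capacity(g_obs.n_nodes, len(arcs0))
    st = _core.build_state(g_obs.n_nodes, arcs0, cap)
    mdl = _core.encode_model(model, attrs, g_obs.n_nodes)
    p = len(model)
    theta = np.zeros(p)
    v = 0.0
    L0 = len(arcs0)
    mode = 0 if cfg.sampler_mode == "basic" else 1
    _core.seed_rng(seed)
    for _ in range(cfg.cd_updates):
        dz = np.zeros(p)
        v = _core._cd_chain(st, mdl, theta, dz, cfg.cd_steps, mode, L0, v,
                            cfg.ifd_adapt_rate)
        theta = _update_theta(theta, dz, cfg.cd_learning_rate,
                              cfg.theta_min, cfg.update_rule)
        if not np.all(np.isfinite(theta)):
            raise InitializationError(
                "CD initialization produced non-finite parameters")
    return theta, v


def ee_estimate(g_obs: DirectedGraph, model: ModelSpec,
                attrs: Optional[AttributeSet], theta0, cfg: EEConfig,
                seed: Optional[int] = None, ifd_v0: float = 0.0
                ) -> EERunResult:
    """One EE estimation run from a single persistent chain started at the
    observed network (the caller's graph is never mutated)."""
    theta0 = np.asarray(theta0, dtype=np.float64)
    if len(theta0) != len(model):
        raise ValueError("theta0 length must match the number of effects")
    if not np.all(np.isfinite(theta0)):
        raise ValueError("theta0 must be finite")
    if seed is None:
        seed = cfg.seed
    arcs0 = g_obs.arcs_array()
    cap = cfg.arc_capacity or _core.default_capacity(g_obs.n_nodes, len(arcs0))
    st = _core.build_state(g_obs.n_nodes, arcs0, cap)
    mdl = _core.encode_model(model, attrs, g_obs.n_nodes)
    p = len(model)
    L0 = len(arcs0)
    theta = theta0.copy()
    dz = np.zeros(p)
    v = float(ifd_v0)
    ifd = cfg.sampler_mode == "ifd"
    adapt_until = max(1, cfg.ee_steps // 10) if ifd else 0
    theta_trace = np.full((cfg.ee_steps, p), np.nan)
    dz_trace = np.full((cfg.ee_steps, p), np.nan)
    accepts = 0
    recorded = cfg.ee_steps
    _core.seed_rng(seed)
    for it in range(cfg.ee_steps):
        if ifd:
            acc, v = _core._run_ifd(st, mdl, theta, dz, cfg.steps_per_update,
                                    L0, v, cfg.ifd_adapt_rate,
                                    it < adapt_until)
            _core._ifd_restore(st, mdl, theta, dz, L0, v)
        else:
            acc = _core._run_basic(st, mdl, theta, dz, cfg.steps_per_update)
        accepts += acc
        theta = _update_theta(theta, dz, cfg.learning_rate,
                              cfg.theta_min, cfg.update_rule)
        theta_trace[it] = theta
        dz_trace[it] = dz
        if (not np.all(np.isfinite(theta))
                or np.max(np.abs(theta)) > inference.THETA_LIMIT):
            recorded = it + 1
            break
    theta_trace = theta_trace[:recorded]
    dz_trace = dz_trace[:recorded]
    half = recorded // 2
    theta_hat = theta_trace[half:].mean(axis=0)

    se = np.full(p, np.nan)
    singular = False
    finite = np.all(np.isfinite(theta_trace))
    if finite and recorded - half > p + 2:
        th_half = theta_trace[half:]
        dz_half = dz_trace[half:]
        # statistics held fixed by the sampler (e.g. the arc count under
        # IFD) have zero divergence variance; they carry no Fisher
        # information and get an infinite standard error
        free = dz_half.std(axis=0) > 0
        try:
            if free.all():
                se = inference.run_se(th_half, dz_half)
            else:
                sub = inference.run_se(th_half[:, free], dz_half[:, free])
                se = np.full(p, np.inf)
                se[free] = sub
        except inference.SingularCovarianceError:
            singular = True

    converged, t_ratios = inference.convergence_check(
        dz_trace, theta_trace, singular=singular)
    if np.isnan(se).any():   # inf is allowed (fixed statistic under IFD)
        converged = False
    return EERunResult(
        theta_trace=theta_trace, dz_trace=dz_trace, theta_hat=theta_hat,
        se=se, converged=converged, t_ratios=t_ratios, ifd_v=v,
        accept_rate=accepts / (recorded * cfg.steps_per_update),
        singular=singular)


def run_parallel(g_obs: DirectedGraph, model: ModelSpec,
                 attrs: Optional[AttributeSet], cfg: EEConfig
                 ) -> list[EERunResult]:
    """``cfg.n_runs`` independent estimation runs with distinct seeds.

    Runs are executed sequentially in a deterministic order; per-run seeds
    are spawned from ``cfg.seed`` so results are reproducible and
    independent.  A run whose CD initialization fails is reported as a
    non-converged result rather than raising.
    """
    ss = np.random.SeedSequence(cfg.seed)
    results: list[EERunResult] = []
    p = len(model)
    for child in ss.spawn(cfg.n_runs):
        cd_seed, ee_seed = (int(s) % 2 ** 31 for s in child.generate_state(2))
        try:
            theta0, v0 = _cd_init_full(g_obs, model, attrs, cfg, seed=cd_seed)
            results.append(ee_estimate(g_obs, model, attrs, theta0, cfg,
                                       seed=ee_seed, ifd_v0=v0))
        except InitializationError:
            nanp = np.full(p, np.nan)
            results.append(EERunResult(
                theta_trace=np.empty((0, p)), dz_trace=np.empty((0, p)),
                theta_hat=nanp, se=nanp, converged=False,
                t_ratios=nanp))
    return results
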