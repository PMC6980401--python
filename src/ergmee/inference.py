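"""Standard errors, run combination and convergence verdicts.

Each estimation run yields a parameter trace and a statistic-divergence
trace.  The Monte Carlo covariance of the trace mean is estimated by the
multivariate batch means method; the covariance inherent in using the MLE
is the inverse of the covariance matrix of the simulated statistics
(Fisher information).  The per-run standard error is the square root of
the diagonal of the sum of the two matrices.  Estimates from independent
runs are pooled by inverse-variance weighting.

A run converges when every statistic-divergence t-ratio (mean/sd over the
second half of the trace) is at most 0.3 in absolute value, the parameter
trace is finite and below 1e10 in magnitude, and the simulated-statistic
covariance is not (nearly) singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "batch_means_cov", "mle_cov", "run_se", "combine_runs",
    "convergence_check", "CombinedEstimate", "SingularCovarianceError",
    "T_RATIO_LIMIT", "THETA_LIMIT", "RCOND_LIMIT",
]

T_RATIO_LIMIT = 0.3
THETA_LIMIT = 1e10
RCOND_LIMIT = 1e-12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Simulated-statistic covariance is computationally singular."""


def _as_columns(trace) -> np.ndarray:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim == 1:
        trace = trace[:, None]
    return trace


@dataclass
class CombinedEstimate:
    """Inverse-variance pooled estimate across converged runs."""

    theta_hat: np.ndarray
    se: np.ndarray
    n_converged_runs: int

    @property
    def significant(self) -> np.ndarray:
        """Two-sided p < 0.05 flags: |theta| > 1.96 * se."""
        return np.abs(self.theta_hat) > 1.96 * self.se

    def ci(self, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        return self.theta_hat - z * self.se, self.theta_hat + z * self.se


def batch_means_cov(trace: np.ndarray, min_rows: int = 10) -> np.ndarray:
    """Multivariate batch-means estimate of Cov(mean of the trace).

    The trace is split into floor(sqrt(T)) batches of equal length b
    (trailing rows are used; a short remainder at the start is dropped);
    the covariance of the batch means, scaled by b/T, estimates the Monte
    Carlo covariance of the trace mean.
    """
    trace = _as_columns(trace)
    T, p = trace.shape
    if T < min_rows:
        raise ValueError(f"trace has {T} rows; need at least {min_rows}")
    a = int(np.floor(np.sqrt(T)))
    b = T // a
    used = trace[T - a * b:]
    means = used.reshape(a, b, p).mean(axis=1)
    dev = means - means.mean(axis=0)
    # sample covariance of batch means, scaled by b/T
    cov = dev.T @ dev / (a - 1)
    return cov * b / T


def mle_cov(sim_stats_trace: np.ndarray,
            rcond_limit: float = RCOND_LIMIT) -> np.ndarray:
    """Inverse of the sample covariance of the simulated statistics.

    Raises :class:`SingularCovarianceError` when the covariance is
    (nearly) computationally singular, which the convergence check treats
    as a non-convergence signal (possible model degeneracy).
    """
    trace = _as_columns(sim_stats_trace)
    T, p = trace.shape
    if T <= p:
        raise ValueError(f"need more than {p} rows, got {T}")
    cov = np.cov(trace, rowvar=False).reshape(p, p)
    sv = np.linalg.svd(cov, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < rcond_limit:
        raise SingularCovarianceError(
            "covariance of simulated statistics is (nearly) singular")
    return np.linalg.inv(cov)


def run_se(theta_trace: np.ndarray, sim_stats_trace: np.ndarray) -> np.ndarray:
    """Per-effect standard error for one run:
    sqrt(diag(batch_means_cov(theta) + mle_cov(simulated statistics)))."""
    total = batch_means_cov(theta_trace) + mle_cov(sim_stats_trace)
    return np.sqrt(np.diag(total))


def combine_runs(results) -> CombinedEstimate:
    """Inverse-variance weighted average over converged runs.

    ``results`` is a sequence of objects with ``theta_hat``, ``se`` and
    ``converged`` attributes (non-converged runs are excluded).
    """
    kept = [r for r in results if r.converged]
    if not kept:
        raise ValueError("no converged runs to combine")
    thetas = np.stack([r.theta_hat for r in kept])
    ses = np.stack([r.se for r in kept])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / ses ** 2                    # se = inf contributes weight 0
        wsum = w.sum(axis=0)
        # an effect no run carries information on gets nan / inf
        theta_hat = (w * thetas).sum(axis=0) / wsum
        se = np.sqrt(1.0 / wsum)
    return CombinedEstimate(theta_hat=theta_hat, se=se,
                            n_converged_runs=len(kept))


def convergence_check(dz_trace: np.ndarray, theta_trace: np.ndarray,
                      singular: bool = False,
                      t_ratio_limit: float = T_RATIO_LIMIT
                      ) -> tuple[bool, np.ndarray]:
    """Convergence verdict and per-effect t-ratios.

    t_A = mean(dz_A) / sd(dz_A) over the second half of the divergence
    trace.  Non-convergence is concluded when any |t_A| > 0.3, any
    parameter is NaN or exceeds 1e10 in magnitude, or the simulated-
    statistic covariance was singular.
    """
    dz_trace = _as_columns(dz_trace)
    theta_trace = _as_columns(theta_trace)
    if dz_trace.shape[0] == 0 or theta_trace.shape[0] == 0:
        raise ValueError("traces must be nonempty")
    half = dz_trace[dz_trace.shape[0] // 2:]
    mean = half.mean(axis=0)
    sd = half.std(axis=0, ddof=1) if half.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / sd, np.where(mean == 0, 0.0, np.inf))
    ok = (not singular
          and bool(np.all(np.isfinite(theta_trace)))
          and bool(np.max(np.abs(theta_trace), initial=0.0) <= THETA_LIMIT)
          and bool(np.all(np.isfinite(t)))
          and bool(np.max(np.abs(t)) <= t_ratio_limit))
    return ok, t
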