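"""Vectorized adaptive random-walk Metropolis sampling and convergence checks.

The sampler runs many independent targets at once: the state array carries
leading dimensions (e.g. ``(n_subjects, n_chains)``) and the log-posterior
callable must map ``(..., k)`` parameter arrays to ``(...)`` log densities.
Proposal step sizes adapt per target during warm-up (Robbins–Monro on the
acceptance rate, with per-coordinate scales re-estimated from mid-warm-up
draws) and are frozen afterwards, so the post-warm-up chain is a valid
Metropolis chain.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["sample_rwm", "gelman_rubin"]


def sample_rwm(
    log_post: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    n_samples: int,
    n_warmup: int,
    rng: np.random.Generator,
    init_scales: np.ndarray,
    target_accept: float = 0.3,
    pool_axis: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_samples`` Metropolis iterations, returning post-warm-up draws.

    Parameters
    ----------
    log_post:
        Vectorized log posterior; ``-inf`` encodes constraint violations.
    x0:
        Initial states, shape ``(*lead, k)``.  Each leading element is an
        independent chain (callers put subjects and chains in the lead).
    n_samples, n_warmup:
        Total iterations per chain and the number discarded (and used for
        adaptation) at the start.
    init_scales:
        Per-coordinate proposal scales, shape broadcastable to ``x0``.
    pool_axis:
        Optional leading axis over which warm-up moments are pooled when
        estimating the proposal covariance (e.g. the chain axis: chains of
        one target share a posterior, so pooling sharpens the estimate;
        adaptation ends at warm-up, which keeps the kept draws valid).

    Returns
    -------
    draws : ndarray, shape ``(n_samples - n_warmup, *lead, k)``
    accept_rate : ndarray, shape ``(*lead,)`` post-warm-up acceptance rate.
    """
    if n_warmup >= n_samples:
        raise ValueError("n_warmup must be < n_samples")
    x = np.array(x0, dtype=float, copy=True)
    lead, k = x.shape[:-1], x.shape[-1]
    # proposal shape: step * L z with L the Cholesky factor of an adapted
    # per-target covariance (diagonal init_scales until mid-warm-up)
    chol = np.zeros((*lead, k, k))
    diag = np.broadcast_to(np.asarray(init_scales, float), x.shape)
    idx = np.arange(k)
    chol[..., idx, idx] = diag
    log_step = np.full(lead, np.log(2.38 / np.sqrt(k)))
    lp = log_post(x)
    if np.any(~np.isfinite(lp)):
        raise ValueError("initial state has non-finite log posterior")

    n_keep = n_samples - n_warmup
    draws = np.empty((n_keep, *lead, k))
    accepted = np.zeros(lead)

    # two covariance re-estimations during warm-up: a rough one from draws
    # under the initial diagonal proposal, then a refined one
    updates = {n_warmup // 2: n_warmup // 4, n_warmup: n_warmup // 2}
    mom1 = np.zeros_like(x)
    mom2 = np.zeros((*lead, k, k))
    window_start = n_warmup // 4

    def refresh_covariance(n_w: int) -> None:
        nonlocal chol, mom1, mom2
        m1, m2, n_eff = mom1, mom2, float(n_w)
        if pool_axis is not None:
            n_eff *= lead[pool_axis]
            m1 = m1.sum(axis=pool_axis, keepdims=True)
            m2 = m2.sum(axis=pool_axis, keepdims=True)
            m1 = np.broadcast_to(m1, mom1.shape)
            m2 = np.broadcast_to(m2, mom2.shape)
        else:
            n_eff = n_w
        mean = m1 / n_eff
        cov = m2 / n_eff - mean[..., :, None] * mean[..., None, :]
        cov = cov + 0.0  # materialize from broadcast views
        cov[..., idx, idx] += 1e-6 + 1e-3 * cov[..., idx, idx]
        try:
            chol_new = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return  # keep the previous proposal shape
        ok = np.all(np.isfinite(chol_new), axis=(-2, -1))
        chol = np.where(ok[..., None, None], chol_new, chol)
        log_step[:] = np.log(2.38 / np.sqrt(k))
        mom1 = np.zeros_like(x)
        mom2 = np.zeros((*lead, k, k))

    for t in range(n_samples):
        z = rng.standard_normal(x.shape)
        prop = x + np.exp(log_step)[..., None] * np.einsum("...ij,...j->...i", chol, z)
        lp_prop = log_post(prop)
        accept = np.log(rng.random(lead)) < lp_prop - lp
        x[accept] = prop[accept]
        lp = np.where(accept, lp_prop, lp)

        if t < n_warmup:
            gamma = 2.0 / (t + 10.0) ** 0.7
            log_step += gamma * (accept.astype(float) - target_accept)
            if t >= window_start:
                mom1 += x
                mom2 += x[..., :, None] * x[..., None, :]
            if t + 1 in updates:
                n_w = (t + 1) - window_start
                if n_w > 2 * k:
                    refresh_covariance(n_w)
                window_start = t + 1
        else:
            accepted += accept
            draws[t - n_warmup] = x

    return draws, accepted / n_keep


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` has shape ``(n_chains, n_iterations)`` (post-warm-up draws,
    equal lengths).  Computes the classic between/within-chain variance
    ratio: ``sqrt(((n-1)/n * W + B/n) / W)``.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (n_chains, n_iterations) array")
    m, n = arr.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 2:
        raise ValueError("R-hat requires at least 2 iterations per chain")
    chain_means = arr.mean(axis=1)
    within = arr.var(axis=1, ddof=1).mean()
    between = n * chain_means.var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))
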