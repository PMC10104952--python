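"""Adaptive random-walk Metropolis engine.

All posteriors in this package are sampled on an unconstrained scale with a
Gaussian random-walk proposal whose scale and covariance adapt during warmup
(Robbins–Monro step-size tuning toward a target acceptance rate, combined with
Haario-style empirical-covariance adaptation).  Adaptation is frozen after
warmup so the kept draws come from a fixed, valid Markov kernel.

The hierarchical models in :mod:`contextfx.hierarchical` only ever need this
engine on their 1–4 dimensional *collapsed* hyperparameter posteriors; the
individual-level rates are conjugate given the hyperparameters and are drawn
exactly afterwards.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def run_chain(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_warmup: int,
    n_kept: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
    thin: int = 1,
) -> tuple[np.ndarray, float]:
    """Run one adaptive random-walk Metropolis chain.

    After warmup, every ``thin``-th state is retained until ``n_kept`` draws
    are collected (thinning trades cheap iterations for decorrelated draws).
    Returns the kept draws ``(n_kept, k)`` and the post-warmup acceptance
    rate.  ``logpost`` must return ``-inf`` (never NaN) outside the support.
    """
    x = np.asarray(x0, dtype=float).copy()
    k = x.size
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    scale = 2.38 / np.sqrt(k)
    chol = np.eye(k)
    history = np.empty((n_warmup, k))
    draws = np.empty((n_kept, k))
    n_accept_kept = 0

    for t in range(n_warmup + n_kept * thin):
        step = scale * (chol @ rng.standard_normal(k))
        prop = x + step
        lpp = float(logpost(prop))
        log_alpha = lpp - lp
        accept_prob = 1.0 if log_alpha >= 0 else np.exp(log_alpha)
        if np.log(rng.random()) < log_alpha:
            x, lp = prop, lpp
            accepted = True
        else:
            accepted = False

        if t < n_warmup:
            history[t] = x
            # Robbins-Monro on the log step size toward the target acceptance
            scale *= np.exp((accept_prob - target_accept) / (t + 1) ** 0.6)
            scale = float(np.clip(scale, 1e-6, 1e3))
            if t >= 99 and (t + 1) % 50 == 0:
                cov = np.atleast_2d(np.cov(history[(t + 1) // 2:t + 1].T))
                cov += 1e-8 * np.eye(k)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    chol = np.eye(k)
        else:
            post = t - n_warmup
            if post % thin == thin - 1:
                draws[post // thin] = x
            n_accept_kept += accepted

    return draws, n_accept_kept / max(n_kept * thin, 1)


def run_chains(
    logpost: Callable[[np.ndarray], float],
    inits: np.ndarray,
    n_warmup: int,
    n_kept: int,
    seeds: list,
    target_accept: float = 0.3,
    thin: int = 1,
) -> tuple[np.ndarray, float]:
    """Run several chains from distinct initial points and stack the draws.

    ``inits`` has shape ``(n_chains, k)``; ``seeds`` is one RNG seed per chain.
    Returns draws ``(n_chains, n_kept, k)`` and the mean acceptance rate.
    """
    inits = np.atleast_2d(np.asarray(inits, dtype=float))
    n_chains = inits.shape[0]
    all_draws = np.empty((n_chains, n_kept, inits.shape[1]))
    rates = []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        all_draws[c], rate = run_chain(logpost, inits[c], n_warmup, n_kept, rng,
                                       target_accept=target_accept, thin=thin)
        rates.append(rate)
    return all_draws, float(np.mean(rates))
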