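"""Bayesian correlations between context effects across participants.

A positive attraction–compromise correlation and negative correlations of
both with the similarity effect are a recurring pattern in two-triplet
studies and constrain theories of the underlying mechanism.  Here each
participant contributes one choice-share value per effect, and pairs of
effects are modeled as draws from a bivariate normal; the posterior of the
correlation parameter ``rho`` is summarized by its mean and 95% HDI.

Priors are weakly informative: Normal(0, 100) on the marginal means,
half-normal (scale 10) on the marginal SDs, and uniform on ``rho`` over
(-1, 1).  Sampling runs on an unconstrained scale (log SDs, atanh rho) via
the package's adaptive Metropolis engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._mcmc import run_chains
from .choice_data import ContextCounts
from .evidence import hdi as _hdi
from .hierarchical import SamplerConfig, _chain_seeds, _compute_rhat
from .measures import DegenerateSampleError, rst_ew, rst_uw

__all__ = ["CorrelationResult", "participant_effect_values", "correlate_effects"]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """No participants with complete data for the requested pair."""


@dataclass(frozen=True)
class CorrelationResult:
    r_mean: float
    hdi: tuple[float, float]
    draws: np.ndarray
    rhat: float


def participant_effect_values(
    counts: Mapping[tuple[str, str], ContextCounts],
    measure: str = "rst_ew",
) -> pd.DataFrame:
    """Per-participant choice-share values, one column per effect.

    Applies ``rst_uw`` or ``rst_ew`` to every (participant, effect) cell;
    cells where the measure is undefined are dropped with a log entry.
    Participants missing an effect get NaN in that column (pairwise-complete
    selection is left to :func:`correlate_effects` callers).
    """
    fn = {"rst_uw": rst_uw, "rst_ew": rst_ew}[measure]
    values: dict[str, dict[str, float]] = {}
    for (pid, effect), c in counts.items():
        try:
            values.setdefault(pid, {})[effect] = fn(c).value
        except (DegenerateSampleError, ValueError):
            logger.info("dropping (%s, %s): measure undefined", pid, effect)
    frame = pd.DataFrame.from_dict(values, orient="index").sort_index()
    frame.index.name = "participant_id"
    return frame


def _bivariate_logpost(X, data):
    """Unnormalized log posterior of (m1, m2, log s1, log s2, atanh rho)."""
    X = np.atleast_2d(X)
    m1, m2 = X[:, 0], X[:, 1]
    ls1, ls2, z = X[:, 2], X[:, 3], X[:, 4]
    s1 = np.exp(np.clip(ls1, -300, 300))
    s2 = np.exp(np.clip(ls2, -300, 300))
    rho = np.tanh(z)
    n = data.shape[0]
    d1 = (data[None, :, 0] - m1[:, None]) / s1[:, None]
    d2 = (data[None, :, 1] - m2[:, None]) / s2[:, None]
    one_m_r2 = 1 - rho**2
    with np.errstate(all="ignore"):
        quad = (d1**2 - 2 * rho[:, None] * d1 * d2 + d2**2).sum(axis=1)
        ll = (-n * np.log(2 * np.pi) - n * (ls1 + ls2)
              - 0.5 * n * np.log(one_m_r2) - quad / (2 * one_m_r2))
        # priors: Normal(0, 100) means; half-normal(10) SDs (+log jacobian);
        # uniform rho (+atanh jacobian log(1 - rho^2))
        lp = ll - (m1**2 + m2**2) / (2 * 100.0**2)
        lp += -(s1**2 + s2**2) / (2 * 10.0**2) + ls1 + ls2
        lp += np.log(one_m_r2)
    lp[~np.isfinite(lp)] = -np.inf
    return lp


def correlate_effects(x, y, config: SamplerConfig | None = None,
                      seed: int = 0, hdi_mass: float = 0.95) -> CorrelationResult:
    """Posterior of the correlation between two per-participant effect series.

    ``x`` and ``y`` are paired values (same participants, same order).
    Requires n >= 3 and nonzero variance in both margins.
    """
    config = config or SamplerConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    data = np.column_stack([x[mask], y[mask]])
    if data.shape[0] < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {data.shape[0]}")
    if np.ptp(data[:, 0]) == 0 or np.ptp(data[:, 1]) == 0:
        raise DegenerateSampleError("zero variance in a margin")

    r0 = np.corrcoef(data.T)[0, 1]
    base = np.array([data[:, 0].mean(), data[:, 1].mean(),
                     np.log(data[:, 0].std(ddof=1)),
                     np.log(data[:, 1].std(ddof=1)),
                     np.arctanh(np.clip(r0, -0.99, 0.99))])
    rng = np.random.default_rng(seed)
    inits = base[None, :] + 0.1 * rng.standard_normal((config.n_chains, 5))

    def logpost(v):
        return _bivariate_logpost(v[None, :], data)[0]

    draws, _ = run_chains(logpost, inits, config.n_warmup, config.n_kept,
                          _chain_seeds(seed, config.n_chains),
                          config.target_accept, thin=config.thin)
    r_draws = np.tanh(draws[:, :, 4])
    rhat = _compute_rhat({"rho": r_draws})["rho"]
    flat = r_draws.reshape(-1)
    return CorrelationResult(r_mean=float(flat.mean()),
                             hdi=_hdi(flat, mass=hdi_mass),
                             draws=flat, rhat=float(rhat))
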