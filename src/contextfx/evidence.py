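"""Inference from posterior draws: marginal likelihoods, Bayes factors,
highest density intervals, and categorical decisions.

Marginal likelihoods are estimated by the iterative optimal-bridge estimator
(Meng–Wong fixed point) with a moment-matched multivariate-normal proposal:
half of the posterior draws fit the proposal, the other half enter the bridge
iteration.  Bayes factors compare the alternative model (group mean free)
against the constrained null; the conventional evidence thresholds are
BF10 >= 3 (support for the alternative) and BF10 <= 1/3 (support for the
null).  HDI-based decisions ask whether 0.5 lies outside the 95% highest
density interval of the group-level choice share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .choice_data import SchemaError
from .hierarchical import (PosteriorSamples, PriorSpec, SamplerConfig,
                           fit_rst_ew, fit_rst_uw)

__all__ = [
    "BridgeResult", "EvidenceResult", "BridgeConvergenceError",
    "bridge_logml", "marginal_likelihood", "bayes_factor", "hdi",
    "decide", "decide_bf", "decide_hdi", "group_rst_from_posterior",
    "rst_evidence",
]


class BridgeConvergenceError(RuntimeError):
    """The bridge fixed point failed to converge; carries the iterate trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class InsufficientSampleError(ValueError):
    """Too few draws for the requested interval."""


@dataclass(frozen=True)
class BridgeResult:
    """Log marginal likelihood with a relative-error estimate."""

    logml: float
    rel_err: float
    n_iter: int
    n_posterior: int
    n_proposal: int


@dataclass
class EvidenceResult:
    """Bayes-factor and HDI evidence for one effect under one measure."""

    measure_kind: str
    logml_alt: float
    logml_null: float
    logml_alt_err: float
    logml_null_err: float
    bf10: float
    log10_bf10: float
    hdi: tuple[float, float]
    decision_bf: str
    decision_hdi: str
    diagnostics: dict = field(default_factory=dict)


def _mvn_fit(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    mean = draws.mean(axis=0)
    cov = np.atleast_2d(np.cov(draws.T))
    regularized = False
    ridge = 0.0
    for _ in range(10):
        try:
            chol = np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
            return mean, chol, regularized
        except np.linalg.LinAlgError:
            regularized = True
            ridge = max(ridge * 10, 1e-10 * max(np.trace(cov), 1.0))
    raise np.linalg.LinAlgError("proposal covariance could not be factorized")


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
    z = np.linalg.solve(chol, (x - mean).T)
    logdet = np.sum(np.log(np.diag(chol)))
    k = mean.size
    return -0.5 * np.sum(z * z, axis=0) - logdet - 0.5 * k * np.log(2 * np.pi)


def bridge_logml(draws: np.ndarray, log_density, seed: int = 0,
                 tol: float = 1e-10, max_iter: int = 1000) -> BridgeResult:
    """Optimal-bridge estimate of a log normalizing constant.

    Parameters
    ----------
    draws
        Posterior draws on the unconstrained scale, shape ``(n, k)`` (or
        ``(n,)`` for a scalar parameter).  The first half fits the
        multivariate-normal proposal; the second half enters the estimator.
    log_density
        Vectorized unnormalized log density: maps ``(m, k)`` to ``(m,)``.
    seed
        Seed for the proposal draws.

    Returns the log marginal likelihood with an approximate relative error
    (iid formula).  Raises :class:`BridgeConvergenceError` if the fixed point
    does not settle within ``max_iter`` iterations.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    n = draws.shape[0]
    half = n // 2
    fit_draws, est_draws = draws[:half], draws[half:]
    mean, chol, _ = _mvn_fit(fit_draws)

    n1 = est_draws.shape[0]
    n2 = n1
    rng = np.random.default_rng(seed)
    proposal = mean + (chol @ rng.standard_normal((mean.size, n2))).T

    with np.errstate(all="ignore"):
        l1 = np.asarray(log_density(est_draws)) - _mvn_logpdf(est_draws, mean, chol)
        l2 = np.asarray(log_density(proposal)) - _mvn_logpdf(proposal, mean, chol)
    l2 = l2[np.isfinite(l2)]  # proposal may land outside the support
    n2_eff = l2.size
    if n2_eff == 0:
        raise BridgeConvergenceError("no proposal draw fell in the support", [])
    log_s1 = np.log(n1 / (n1 + n2_eff))
    log_s2 = np.log(n2_eff / (n1 + n2_eff))

    r = logsumexp(l2) - np.log(n2_eff)  # importance-sampling start
    trace = [float(r)]
    converged = False
    for it in range(max_iter):
        log_num = logsumexp(l2 - np.logaddexp(log_s1 + l2, log_s2 + r)) - np.log(n2_eff)
        log_den = logsumexp(-np.logaddexp(log_s1 + l1, log_s2 + r)) - np.log(n1)
        r_new = log_num - log_den
        trace.append(float(r_new))
        if abs(r_new - r) <= tol * max(1.0, abs(r_new)):
            converged = True
            r = r_new
            break
        r = r_new
    if not converged:
        raise BridgeConvergenceError(
            f"bridge fixed point did not converge in {max_iter} iterations", trace)

    # iid relative-MSE approximation at the fixed point
    u2 = np.exp(l2 - r)
    f1 = u2 / (np.exp(log_s1) * u2 + np.exp(log_s2))
    u1 = np.exp(l1 - r)
    f2 = 1.0 / (np.exp(log_s1) * u1 + np.exp(log_s2))
    re2 = (np.var(f1) / (n2_eff * np.mean(f1) ** 2)
           + np.var(f2) / (n1 * np.mean(f2) ** 2))
    return BridgeResult(logml=float(r), rel_err=float(np.sqrt(max(re2, 0.0))),
                        n_iter=len(trace) - 1, n_posterior=n1, n_proposal=n2_eff)


def marginal_likelihood(samples: PosteriorSamples, seed: int = 0,
                        **kwargs) -> BridgeResult:
    """Bridge-sampling marginal likelihood of a fitted hierarchical model.

    Uses the collapsed hyperparameter draws and matching collapsed density
    stored on the fit; the individual-level rates are already integrated out
    analytically, so the marginal likelihood is that of the full hierarchy.
    """
    return bridge_logml(samples.unconstrained_matrix(),
                        samples.collapsed_logpost, seed=seed, **kwargs)


def bayes_factor(logml_alt: float, logml_null: float) -> tuple[float, float]:
    """Bayes factor BF10 = exp(logml_alt - logml_null) and its log10."""
    if not (np.isfinite(logml_alt) and np.isfinite(logml_null)):
        raise ValueError("log marginal likelihoods must be finite")
    diff = logml_alt - logml_null
    return float(np.exp(diff)), float(diff / np.log(10.0))


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the draws.

    Assumes a unimodal distribution (all posteriors in this package are).
    Requires at least 100 draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    window = int(np.ceil(mass * n))
    if n < 100 or window >= n + 1:
        raise InsufficientSampleError(f"need >= 100 draws, got {n}")
    if window == n:
        return float(x[0]), float(x[-1])
    widths = x[window - 1:] - x[:n - window + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + window - 1])


def decide_bf(bf10: float, threshold: float = 3.0) -> str:
    """Categorical decision from a Bayes factor at symmetric thresholds."""
    if bf10 >= threshold:
        return "supports_alternative"
    if bf10 <= 1.0 / threshold:
        return "supports_null"
    return "inconclusive"


def decide_hdi(interval: tuple[float, float], null_value: float = 0.5,
               direction: str = "two_sided") -> str:
    """Does the HDI exclude the null value (respecting the test direction)?"""
    lo, hi = interval
    if direction == "greater":
        excluded = lo > null_value
    else:
        excluded = (null_value < lo) or (null_value > hi)
    return "hdi_excludes_null" if excluded else "hdi_includes_null"


def decide(evidence: EvidenceResult, rule: str = "bf_threshold",
           direction: str = "two_sided", bf_threshold: float = 3.0,
           null_value: float = 0.5) -> str:
    """Apply a decision rule to an :class:`EvidenceResult`."""
    if rule == "bf_threshold":
        return decide_bf(evidence.bf10, threshold=bf_threshold)
    if rule == "hdi_exclusion":
        return decide_hdi(evidence.hdi, null_value=null_value, direction=direction)
    raise ValueError(f"unknown rule {rule!r}")


def group_rst_from_posterior(samples: PosteriorSamples,
                             measure_kind: str) -> np.ndarray:
    """Draws of the group-level choice share implied by a fitted model.

    ``rst_uw``: the group mean directly; ``rst_ew``: the average of the two
    per-context group means; ``ast``/``asc``: the averaged target/competitor
    components of the two simplex means.
    """
    try:
        if measure_kind == "rst_uw":
            return samples.stacked("mu")
        if measure_kind == "rst_ew":
            return 0.5 * (samples.stacked("mu_C1") + samples.stacked("mu_C2"))
        if measure_kind in ("ast", "asc"):
            j = 0 if measure_kind == "ast" else 1
            return 0.5 * (samples.stacked("mu_C1")[:, j]
                          + samples.stacked("mu_C2")[:, j])
    except KeyError as err:
        raise SchemaError(f"posterior lacks parameter {err} "
                          f"required for {measure_kind}") from err
    raise ValueError(f"unknown measure kind {measure_kind!r}")


def rst_evidence(y, N, measure: str = "rst_ew",
                 priors: PriorSpec | None = None,
                 config: SamplerConfig | None = None,
                 seed: int = 0, hdi_mass: float = 0.95,
                 bf_threshold: float = 3.0,
                 direction: str = "two_sided") -> EvidenceResult:
    """Full Bayes-factor + HDI analysis of one RST measure on count data.

    Fits the alternative and null hierarchies, bridges both marginal
    likelihoods, and summarizes the group-level share from the alternative
    fit.  ``measure`` is ``"rst_uw"`` (``y``/``N`` pooled per participant) or
    ``"rst_ew"`` (``y``/``N`` of shape ``(n, 2)``).
    """
    fit = fit_rst_uw if measure == "rst_uw" else fit_rst_ew
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4)
    alt = fit(y, N, "alternative", priors, config, seed=int(sub[0]))
    null = fit(y, N, "null", priors, config, seed=int(sub[1]))
    ml_alt = marginal_likelihood(alt, seed=int(sub[2]))
    ml_null = marginal_likelihood(null, seed=int(sub[3]))
    bf10, log10_bf = bayes_factor(ml_alt.logml, ml_null.logml)
    group = group_rst_from_posterior(alt, measure)
    interval = hdi(group, mass=hdi_mass)
    result = EvidenceResult(
        measure_kind=measure,
        logml_alt=ml_alt.logml, logml_null=ml_null.logml,
        logml_alt_err=ml_alt.rel_err, logml_null_err=ml_null.rel_err,
        bf10=bf10, log10_bf10=log10_bf, hdi=interval,
        decision_bf=decide_bf(bf10, bf_threshold),
        decision_hdi=decide_hdi(interval, direction=direction),
        diagnostics={
            "rhat_alt": alt.max_rhat, "rhat_null": null.max_rhat,
            "accept_alt": alt.accept_rate, "accept_null": null.accept_rate,
            "warnings": alt.warnings + null.warnings,
        },
    )
    return result
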