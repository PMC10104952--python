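"""Hierarchical Bayesian models for relative and absolute choice shares.

Three model families are implemented.

RST_UW
    Each participant's pooled target count (over both contexts) is binomial
    with rate ``theta_i``; the rates follow a group beta distribution with
    mean ``mu`` and concentration ``kappa`` (shapes ``a = mu*kappa``,
    ``b = (1-mu)*kappa``).  The null model fixes ``mu = 0.5``.

RST_EW
    An independent beta-binomial hierarchy per context, with group means
    ``mu_C1, mu_C2`` and concentrations ``kappa_C1, kappa_C2``.  The null
    model constrains ``mu_C2 = 1 - mu_C1`` (the average share is 0.5); the
    concentrations remain free.

AST/ASC
    Per context, each participant's three choice counts (target, competitor,
    decoy) are multinomial with a simplex rate vector drawn from a group
    Dirichlet with simplex mean ``mu_vec`` and concentration ``kappa``.

Default priors: Beta(2, 2) on group means, Dirichlet(2, 2, 2) on simplex
means, and Gamma(shape=0.001, rate=0.001) on concentrations.

Sampling strategy
-----------------
The individual-level rates are conjugate given the hyperparameters, so the
hyperparameters are sampled from their *collapsed* posterior (individual
rates integrated out in closed form — beta-binomial / Dirichlet-multinomial
likelihoods) by adaptive random-walk Metropolis on an unconstrained scale
(logit for means, log for concentrations, additive-log-ratio for simplexes,
with Jacobian corrections).  Individual rates are then drawn exactly from
their conjugate conditional for each kept draw.  The collapsed unconstrained
posterior is also what bridge sampling integrates, which keeps the bridge
low-dimensional; the marginal likelihood is unchanged by the collapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import betaln, expit, gammaln, logit

from ._mcmc import run_chains

__all__ = [
    "PriorSpec", "SamplerConfig", "PosteriorSamples",
    "RstUwParams", "RstEwParams", "AstParams",
    "log_density_rst_uw", "log_density_rst_ew", "log_density_ast",
    "fit_rst_uw", "fit_rst_ew", "fit_ast", "sample_posterior",
]

KAPPA_FLOOR = 1e-6
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors: beta shape pair for means, gamma shape–rate for
    concentrations, Dirichlet pseudo-counts for simplex means."""

    mu_beta: tuple[float, float] = (2.0, 2.0)
    kappa_gamma: tuple[float, float] = (0.001, 0.001)
    dirichlet: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if min(*self.mu_beta, *self.kappa_gamma, *self.dirichlet) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; the default keeps 3 chains of 1500 with 500 warmup.

    ``thin`` inserts extra Metropolis steps between retained draws; iterations
    are cheap (one vectorized collapsed-likelihood evaluation) and thinning
    keeps the retained draws close to independent.
    """

    n_chains: int = 3
    n_warmup: int = 500
    n_kept: int = 1000
    target_accept: float = 0.3
    thin: int = 8

    @classmethod
    def reduced(cls) -> "SamplerConfig":
        """Lighter preset for large simulation sweeps."""
        return cls(n_chains=3, n_warmup=300, n_kept=500, thin=4)


@dataclass
class PosteriorSamples:
    """Posterior draws on the constrained scale plus diagnostics.

    ``posterior`` maps parameter names to ``(chain, draw[, ...])`` arrays.
    ``unconstrained`` holds the free hyperparameter draws
    ``(chain, draw, k)`` on the sampling scale, and ``collapsed_logpost`` the
    matching vectorized unnormalized log posterior — together these are the
    inputs bridge sampling needs.
    """

    posterior: dict[str, np.ndarray]
    unconstrained: np.ndarray
    unconstrained_names: tuple[str, ...]
    collapsed_logpost: Callable[[np.ndarray], np.ndarray]
    n_chains: int
    n_warmup: int
    n_kept: int
    rhat: dict[str, np.ndarray]
    accept_rate: float
    model: str = ""
    hypothesis: str = ""
    warnings: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def unconstrained_matrix(self) -> np.ndarray:
        return self.unconstrained.reshape(-1, self.unconstrained.shape[-1])

    @property
    def max_rhat(self) -> float:
        vals = [np.nanmax(v) for v in self.rhat.values() if np.size(v)]
        return float(np.nanmax(vals)) if vals else float("nan")

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD


# ---------------------------------------------------------------------------
# parameter containers and full joint log densities (constrained scale)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RstUwParams:
    mu: float
    kappa: float
    theta: np.ndarray  # (n,)


@dataclass(frozen=True)
class RstEwParams:
    mu: tuple[float, float]
    kappa: tuple[float, float]
    theta: np.ndarray  # (n, 2)


@dataclass(frozen=True)
class AstParams:
    mu: np.ndarray     # (2, 3) simplex per context
    kappa: tuple[float, float]
    theta: np.ndarray  # (n, 2, 3)


def _beta_logpdf(x, a, b):
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def _binom_logpmf(y, n, p):
    return (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * np.log(p) + (n - y) * np.log1p(-p))


def _hierarchy_logdensity(theta, y, N, mu, kappa) -> float:
    """Binomial likelihood plus beta population density for one hierarchy."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        return -np.inf
    a, b = mu * kappa, (1 - mu) * kappa
    total = np.sum(_binom_logpmf(y, N, theta)) + np.sum(_beta_logpdf(theta, a, b))
    return float(total)


def log_density_rst_uw(params: RstUwParams, y, N,
                       hypothesis: str = "alternative",
                       priors: PriorSpec | None = None) -> float:
    """Joint log density (nats) of the RST_UW hierarchy at ``params``.

    Under the null the group mean is fixed at 0.5 and carries no prior term.
    Out-of-support parameters give ``-inf``, never an exception or NaN.
    """
    priors = priors or PriorSpec()
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    mu = 0.5 if hypothesis == "null" else params.mu
    kappa = params.kappa
    if not (0 < mu < 1) or kappa <= 0:
        return -np.inf
    total = _hierarchy_logdensity(params.theta, y, N, mu, kappa)
    if not np.isfinite(total):
        return -np.inf
    total += _gamma_logpdf(kappa, *priors.kappa_gamma)
    if hypothesis != "null":
        total += _beta_logpdf(mu, *priors.mu_beta)
    return float(total)


def log_density_rst_ew(params: RstEwParams, y, N,
                       hypothesis: str = "alternative",
                       priors: PriorSpec | None = None) -> float:
    """Joint log density of the two-context RST_EW hierarchy.

    ``y`` and ``N`` have shape ``(n, 2)``.  The null variant derives
    ``mu_2 = 1 - mu_1`` from the single free mean; both concentrations stay
    free in either variant.
    """
    priors = priors or PriorSpec()
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    mu1 = params.mu[0]
    mu2 = (1 - mu1) if hypothesis == "null" else params.mu[1]
    if not (0 < mu1 < 1 and 0 < mu2 < 1):
        return -np.inf
    if params.kappa[0] <= 0 or params.kappa[1] <= 0:
        return -np.inf
    total = 0.0
    for s, mu_s in enumerate((mu1, mu2)):
        part = _hierarchy_logdensity(params.theta[:, s], y[:, s], N[:, s],
                                     mu_s, params.kappa[s])
        if not np.isfinite(part):
            return -np.inf
        total += part + _gamma_logpdf(params.kappa[s], *priors.kappa_gamma)
    total += _beta_logpdf(mu1, *priors.mu_beta)
    if hypothesis != "null":
        total += _beta_logpdf(mu2, *priors.mu_beta)
    return float(total)


def log_density_ast(params: AstParams, counts,
                    priors: PriorSpec | None = None) -> float:
    """Joint log density of the Dirichlet-multinomial hierarchy.

    ``counts`` has shape ``(n, 2, 3)`` — per participant, per context, the
    (target, competitor, decoy) frequencies.
    """
    priors = priors or PriorSpec()
    counts = np.asarray(counts, float)
    alpha0 = np.asarray(priors.dirichlet, float)
    total = 0.0
    for s in range(2):
        mu_s = np.asarray(params.mu[s], float)
        kappa_s = params.kappa[s]
        theta_s = np.asarray(params.theta[:, s, :], float)
        if kappa_s <= 0 or np.any(mu_s <= 0) or abs(mu_s.sum() - 1) > 1e-8:
            return -np.inf
        if np.any(theta_s <= 0) or np.any(np.abs(theta_s.sum(axis=1) - 1) > 1e-8):
            return -np.inf
        x = counts[:, s, :]
        n_tot = x.sum(axis=1)
        log_mult = (gammaln(n_tot + 1) - gammaln(x + 1).sum(axis=1)
                    + (x * np.log(theta_s)).sum(axis=1))
        alpha = mu_s * kappa_s
        log_dir = (gammaln(kappa_s) - gammaln(alpha).sum()
                   + ((alpha - 1) * np.log(theta_s)).sum(axis=1))
        part = log_mult.sum() + log_dir.sum()
        if not np.isfinite(part):
            return -np.inf
        total += part
        total += (gammaln(alpha0.sum()) - gammaln(alpha0).sum()
                  + ((alpha0 - 1) * np.log(mu_s)).sum())
        total += _gamma_logpdf(kappa_s, *priors.kappa_gamma)
    return float(total) if np.isfinite(total) else -np.inf


# ---------------------------------------------------------------------------
# collapsed (marginalized) log posteriors on the unconstrained scale
# ---------------------------------------------------------------------------

def _betabinom_loglik(a, b, y, N):
    """Sum over participants of beta-binomial log pmfs.

    ``a``, ``b`` are column vectors ``(m, 1)``; ``y``, ``N`` row data.
    """
    lchoose = gammaln(N + 1) - gammaln(y + 1) - gammaln(N - y + 1)
    return np.sum(lchoose + betaln(y + a, N - y + b) - betaln(a, b), axis=-1)


def _mu_prior_and_jac(logit_mu, mu, ab):
    a, b = ab
    # Beta prior density in mu plus the logit-transform Jacobian log(mu(1-mu));
    # written directly in terms of logit_mu for stability in the tails.
    return (a * np.log(mu) + b * np.log1p(-mu) - betaln(a, b))


def _kappa_prior_and_jac(log_kappa, kappa, shape_rate):
    shape, rate = shape_rate
    # Gamma prior density in kappa plus the log-transform Jacobian log(kappa).
    return (shape * np.log(rate) - gammaln(shape)
            + shape * log_kappa - rate * kappa)


def _safe_mu_kappa(logit_mu, log_kappa):
    mu = expit(logit_mu)
    kappa = np.exp(np.clip(log_kappa, -700, 600))
    ok = (mu > 0) & (mu < 1) & (kappa >= KAPPA_FLOOR) & np.isfinite(kappa)
    return mu, kappa, ok


def collapsed_logpost_rst_uw(X, y, N, hypothesis: str = "alternative",
                             priors: PriorSpec | None = None) -> np.ndarray:
    """Unnormalized log posterior of the RST_UW hyperparameters.

    ``X`` has rows ``(logit mu, log kappa)`` (alternative) or ``(log kappa,)``
    (null, mean fixed at 0.5); individual rates are integrated out.
    """
    priors = priors or PriorSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, float)[None, :]
    N = np.asarray(N, float)[None, :]
    out = np.full(X.shape[0], -np.inf)
    if hypothesis == "null":
        mu, kappa, ok = _safe_mu_kappa(np.zeros(X.shape[0]), X[:, 0])
    else:
        mu, kappa, ok = _safe_mu_kappa(X[:, 0], X[:, 1])
    if not np.any(ok):
        return out
    mu_ok, ka_ok = mu[ok], kappa[ok]
    a = (mu_ok * ka_ok)[:, None]
    b = ((1 - mu_ok) * ka_ok)[:, None]
    with np.errstate(all="ignore"):
        lp = _betabinom_loglik(a, b, y, N)
        lp += _kappa_prior_and_jac(np.log(ka_ok), ka_ok, priors.kappa_gamma)
        if hypothesis != "null":
            lp += _mu_prior_and_jac(X[ok, 0], mu_ok, priors.mu_beta)
    lp[~np.isfinite(lp)] = -np.inf
    out[ok] = lp
    return out


def collapsed_logpost_rst_ew(X, y, N, hypothesis: str = "alternative",
                             priors: PriorSpec | None = None) -> np.ndarray:
    """Unnormalized log posterior of the RST_EW hyperparameters.

    Alternative rows: ``(logit mu1, logit mu2, log k1, log k2)``;
    null rows: ``(logit mu1, log k1, log k2)`` with ``mu2 = 1 - mu1``.
    """
    priors = priors or PriorSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    out = np.full(X.shape[0], -np.inf)
    if hypothesis == "null":
        lm1 = X[:, 0]
        mu1, k1, ok1 = _safe_mu_kappa(lm1, X[:, 1])
        mu2 = 1 - mu1
        _, k2, ok2 = _safe_mu_kappa(-lm1, X[:, 2])
        lm2 = -lm1
    else:
        lm1, lm2 = X[:, 0], X[:, 1]
        mu1, k1, ok1 = _safe_mu_kappa(lm1, X[:, 2])
        mu2, k2, ok2 = _safe_mu_kappa(lm2, X[:, 3])
    ok = ok1 & ok2 & (mu2 > 0) & (mu2 < 1)
    if not np.any(ok):
        return out
    with np.errstate(all="ignore"):
        lp = _betabinom_loglik((mu1[ok] * k1[ok])[:, None],
                               ((1 - mu1[ok]) * k1[ok])[:, None],
                               y[None, :, 0], N[None, :, 0])
        lp += _betabinom_loglik((mu2[ok] * k2[ok])[:, None],
                                ((1 - mu2[ok]) * k2[ok])[:, None],
                                y[None, :, 1], N[None, :, 1])
        lp += _kappa_prior_and_jac(np.log(k1[ok]), k1[ok], priors.kappa_gamma)
        lp += _kappa_prior_and_jac(np.log(k2[ok]), k2[ok], priors.kappa_gamma)
        lp += _mu_prior_and_jac(lm1[ok], mu1[ok], priors.mu_beta)
        if hypothesis != "null":
            lp += _mu_prior_and_jac(lm2[ok], mu2[ok], priors.mu_beta)
    lp[~np.isfinite(lp)] = -np.inf
    out[ok] = lp
    return out


def _alr_inverse(u):
    """Additive-log-ratio inverse: rows ``(u1, u2)`` -> 3-simplex rows."""
    u = np.atleast_2d(u)
    z = np.column_stack([u, np.zeros(u.shape[0])])
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def collapsed_logpost_ast_context(X, counts_c, priors: PriorSpec | None = None
                                  ) -> np.ndarray:
    """Unnormalized log posterior of one context's Dirichlet hyperparameters.

    ``X`` rows are ``(alr1, alr2, log kappa)``; ``counts_c`` is ``(n, 3)``.
    The multinomial simplex rates are integrated out (Dirichlet-multinomial).
    """
    priors = priors or PriorSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    counts_c = np.asarray(counts_c, float)
    out = np.full(X.shape[0], -np.inf)
    mu = _alr_inverse(X[:, :2])
    kappa = np.exp(np.clip(X[:, 2], -700, 600))
    ok = np.all(mu > 0, axis=1) & (kappa >= KAPPA_FLOOR) & np.isfinite(kappa)
    if not np.any(ok):
        return out
    mu_ok = mu[ok]
    ka_ok = kappa[ok]
    alpha = mu_ok * ka_ok[:, None]            # (m, 3)
    x = counts_c[None, :, :]                  # (1, n, 3)
    n_tot = counts_c.sum(axis=1)[None, :]     # (1, n)
    alpha0 = np.asarray(priors.dirichlet, float)
    with np.errstate(all="ignore"):
        log_mult = (gammaln(n_tot + 1) - gammaln(x + 1).sum(axis=2))
        ll = (log_mult
              + gammaln(ka_ok)[:, None] - gammaln(ka_ok[:, None] + n_tot)
              + (gammaln(alpha[:, None, :] + x) - gammaln(alpha[:, None, :])
                 ).sum(axis=2))
        lp = ll.sum(axis=1)
        # Dirichlet(2,2,2) prior on mu plus ALR Jacobian prod(mu_j)
        lp += (gammaln(alpha0.sum()) - gammaln(alpha0).sum()
               + (alpha0 * np.log(mu_ok)).sum(axis=1))
        lp += _kappa_prior_and_jac(np.log(ka_ok), ka_ok, priors.kappa_gamma)
    lp[~np.isfinite(lp)] = -np.inf
    out[ok] = lp
    return out


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

def _chain_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-chain seeds derived from the master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _compute_rhat(posterior: dict[str, np.ndarray],
                  skip: tuple[str, ...] = ()) -> dict[str, np.ndarray]:
    import arviz as az
    out: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = {k: v for k, v in posterior.items() if k not in skip}
        rh = az.rhat(az.from_dict(posterior=data))
        for k in data:
            out[k] = np.asarray(rh[k].values)
    return out


def _finalize(posterior, unconstrained, names, logpost_vec, config, accept,
              model, hypothesis, skip_rhat=()) -> PosteriorSamples:
    rhat = _compute_rhat(posterior, skip=skip_rhat)
    warns = []
    vals = [np.nanmax(v) for v in rhat.values() if np.size(v)]
    if vals and np.nanmax(vals) >= RHAT_THRESHOLD:
        warns.append(f"convergence warning: max Rhat = {np.nanmax(vals):.4f} "
                     f">= {RHAT_THRESHOLD}")
    return PosteriorSamples(
        posterior=posterior, unconstrained=unconstrained,
        unconstrained_names=tuple(names), collapsed_logpost=logpost_vec,
        n_chains=config.n_chains, n_warmup=config.n_warmup,
        n_kept=config.n_kept, rhat=rhat, accept_rate=accept,
        model=model, hypothesis=hypothesis, warnings=warns,
    )


def _validate_counts(y, N):
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    if y.shape != N.shape:
        raise ValueError("y and N must have identical shapes")
    if np.any(y < 0) or np.any(y > N):
        raise ValueError("need 0 <= y <= N elementwise")
    return y, N


def _init_logit_mean(y, N):
    tot_y, tot_n = y.sum(), N.sum()
    p = (tot_y + 1.0) / (tot_n + 2.0) if tot_n > 0 else 0.5
    return float(logit(np.clip(p, 0.02, 0.98)))


def fit_rst_uw(y, N, hypothesis: str = "alternative",
               priors: PriorSpec | None = None,
               config: SamplerConfig | None = None,
               seed: int = 0) -> PosteriorSamples:
    """Sample the RST_UW posterior.

    ``y[i]``/``N[i]`` are participant ``i``'s pooled target successes and
    target+competitor totals.  Returns group mean ``mu`` (fixed 0.5 under the
    null), concentration ``kappa`` and individual rates ``theta``.
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    y, N = _validate_counts(y, N)

    def logpost_vec(X):
        return collapsed_logpost_rst_uw(X, y, N, hypothesis, priors)

    def logpost(x):
        return logpost_vec(x[None, :])[0]

    names = ("log_kappa",) if hypothesis == "null" else ("logit_mu", "log_kappa")
    k = len(names)
    rng = np.random.default_rng(seed)
    base = np.array([np.log(5.0)]) if hypothesis == "null" else \
        np.array([_init_logit_mean(y, N), np.log(5.0)])
    inits = base[None, :] + 0.5 * rng.standard_normal((config.n_chains, k))
    draws, accept = run_chains(logpost, inits, config.n_warmup, config.n_kept,
                               _chain_seeds(seed, config.n_chains),
                               config.target_accept, thin=config.thin)
    if hypothesis == "null":
        mu = np.full(draws.shape[:2], 0.5)
        kappa = np.exp(draws[:, :, 0])
    else:
        mu = expit(draws[:, :, 0])
        kappa = np.exp(draws[:, :, 1])
    # exact conjugate completion of the individual rates
    a = mu * kappa
    b = (1 - mu) * kappa
    theta_rng = np.random.default_rng(_chain_seeds(seed + 1, 1)[0])
    theta = theta_rng.beta(a[..., None] + y, b[..., None] + (N - y))
    posterior = {"mu": mu, "kappa": kappa, "theta": theta}
    skip = ("mu",) if hypothesis == "null" else ()
    return _finalize(posterior, draws, names, logpost_vec, config, accept,
                     "rst_uw", hypothesis, skip_rhat=skip)


def fit_rst_ew(y, N, hypothesis: str = "alternative",
               priors: PriorSpec | None = None,
               config: SamplerConfig | None = None,
               seed: int = 0) -> PosteriorSamples:
    """Sample the RST_EW posterior; ``y``/``N`` have shape ``(n, 2)``."""
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    y, N = _validate_counts(y, N)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("RST_EW expects per-context data with shape (n, 2)")

    def logpost_vec(X):
        return collapsed_logpost_rst_ew(X, y, N, hypothesis, priors)

    def logpost(x):
        return logpost_vec(x[None, :])[0]

    lm1 = _init_logit_mean(y[:, 0], N[:, 0])
    lm2 = _init_logit_mean(y[:, 1], N[:, 1])
    if hypothesis == "null":
        names = ("logit_mu_C1", "log_kappa_C1", "log_kappa_C2")
        base = np.array([0.5 * (lm1 - lm2), np.log(5.0), np.log(5.0)])
    else:
        names = ("logit_mu_C1", "logit_mu_C2", "log_kappa_C1", "log_kappa_C2")
        base = np.array([lm1, lm2, np.log(5.0), np.log(5.0)])
    rng = np.random.default_rng(seed)
    inits = base[None, :] + 0.5 * rng.standard_normal((config.n_chains, len(names)))
    draws, accept = run_chains(logpost, inits, config.n_warmup, config.n_kept,
                               _chain_seeds(seed, config.n_chains),
                               config.target_accept, thin=config.thin)
    if hypothesis == "null":
        mu1 = expit(draws[:, :, 0])
        mu2 = 1 - mu1
        k1 = np.exp(draws[:, :, 1])
        k2 = np.exp(draws[:, :, 2])
    else:
        mu1 = expit(draws[:, :, 0])
        mu2 = expit(draws[:, :, 1])
        k1 = np.exp(draws[:, :, 2])
        k2 = np.exp(draws[:, :, 3])
    theta_rng = np.random.default_rng(_chain_seeds(seed + 1, 1)[0])
    th1 = theta_rng.beta(mu1[..., None] * k1[..., None] + y[:, 0],
                         (1 - mu1[..., None]) * k1[..., None] + N[:, 0] - y[:, 0])
    th2 = theta_rng.beta(mu2[..., None] * k2[..., None] + y[:, 1],
                         (1 - mu2[..., None]) * k2[..., None] + N[:, 1] - y[:, 1])
    posterior = {"mu_C1": mu1, "mu_C2": mu2, "kappa_C1": k1, "kappa_C2": k2,
                 "theta_C1": th1, "theta_C2": th2}
    skip = ("mu_C2",) if hypothesis == "null" else ()
    return _finalize(posterior, draws, names, logpost_vec, config, accept,
                     "rst_ew", hypothesis, skip_rhat=skip)


def fit_ast(counts, priors: PriorSpec | None = None,
            config: SamplerConfig | None = None,
            seed: int = 0) -> PosteriorSamples:
    """Sample the Dirichlet-multinomial posterior; ``counts`` is ``(n, 2, 3)``.

    The two contexts are independent hierarchies and are sampled separately;
    their draws are concatenated into one result.
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    counts = np.asarray(counts, float)
    if counts.ndim != 3 or counts.shape[1:] != (2, 3):
        raise ValueError("AST expects counts with shape (n, 2, 3)")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")

    rng = np.random.default_rng(seed)
    per_context: list[np.ndarray] = []
    accepts = []
    for s in range(2):
        counts_c = counts[:, s, :]

        def lp_vec(X, counts_c=counts_c):
            return collapsed_logpost_ast_context(X, counts_c, priors)

        def lp(x, lp_vec=lp_vec):
            return lp_vec(x[None, :])[0]

        share = (counts_c.sum(axis=0) + 1.0)
        share = share / share.sum()
        base = np.array([np.log(share[0] / share[2]),
                         np.log(share[1] / share[2]), np.log(5.0)])
        inits = base[None, :] + 0.5 * rng.standard_normal((config.n_chains, 3))
        draws, acc = run_chains(lp, inits, config.n_warmup, config.n_kept,
                                _chain_seeds(seed + s, config.n_chains),
                                config.target_accept, thin=config.thin)
        per_context.append(draws)
        accepts.append(acc)

    posterior: dict[str, np.ndarray] = {}
    theta_rng = np.random.default_rng(_chain_seeds(seed + 7, 1)[0])
    for s, draws in enumerate(per_context):
        flat = draws.reshape(-1, 3)
        mu = _alr_inverse(flat[:, :2]).reshape(*draws.shape[:2], 3)
        kappa = np.exp(draws[:, :, 2])
        alpha = mu * kappa[..., None]                        # (C, D, 3)
        post_alpha = alpha[:, :, None, :] + counts[None, None, :, s, :]
        g = theta_rng.gamma(post_alpha)
        theta = g / g.sum(axis=-1, keepdims=True)            # (C, D, n, 3)
        posterior[f"mu_C{s + 1}"] = mu
        posterior[f"kappa_C{s + 1}"] = kappa
        posterior[f"theta_C{s + 1}"] = theta

    unconstrained = np.concatenate(per_context, axis=-1)
    names = ("alr1_C1", "alr2_C1", "log_kappa_C1",
             "alr1_C2", "alr2_C2", "log_kappa_C2")

    def logpost_vec(X):
        return (collapsed_logpost_ast_context(X[:, :3], counts[:, 0, :], priors)
                + collapsed_logpost_ast_context(X[:, 3:], counts[:, 1, :], priors))

    return _finalize(posterior, unconstrained, names, logpost_vec, config,
                     float(np.mean(accepts)), "ast", "alternative")


def sample_posterior(model: str, data, hypothesis: str = "alternative",
                     priors: PriorSpec | None = None,
                     config: SamplerConfig | None = None,
                     seed: int = 0) -> PosteriorSamples:
    """Dispatcher over the three model families.

    ``model`` is ``"rst_uw"`` (data ``(y, N)`` per participant), ``"rst_ew"``
    (data ``(y, N)`` with shape ``(n, 2)``) or ``"ast"`` (data ``(n, 2, 3)``
    count array; no null variant — inference on AST/ASC is HDI-based).
    """
    if model == "rst_uw":
        y, N = data
        return fit_rst_uw(y, N, hypothesis, priors, config, seed)
    if model == "rst_ew":
        y, N = data
        return fit_rst_ew(y, N, hypothesis, priors, config, seed)
    if model == "ast":
        return fit_ast(data, priors, config, seed)
    raise ValueError(f"unknown model {model!r}")
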