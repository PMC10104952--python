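# Methods

## Measures

All four descriptive measures operate on a participant's six choice
frequencies from the two-triplet design.  `rst_uw` is the collapsed-counts
target share; it is algebraically identical to the weighted mean of the two
within-context shares with the context target+competitor totals as weights
(a property-tested invariant).  `rst_ew` is their unweighted mean and is the
recommended measure for independence-of-irrelevant-alternatives (IIA) tests.
`absolute_shares` returns AST and ASC, the target and competitor shares of
*all* choices per context averaged with equal weights; they satisfy
AST + ASC + mean decoy share = 1 exactly and are the appropriate statistics
for regularity tests.  Measures return full precision; rounding to the
conventional two or three decimals happens only at the reporting/CLI layer.

A within-context share is undefined (0/0) when a participant never chose
the target or competitor in that context.  Such cells are excluded from
model fits and logged (`filter_rst_valid`); how the original two-triplet
studies handled this case is not documented, so exclusion is this package's
choice.

## Hierarchical models

**RST_UW.** Participant *i*'s pooled target count is
y_i ~ Binomial(N_i, θ_i) with θ_i ~ Beta(a, b), a = μκ, b = (1−μ)κ.
Hyperpriors: μ ~ Beta(2, 2), κ ~ Gamma(shape = 0.001, rate = 0.001).  The
null model fixes μ = 0.5 (no prior term for μ).

**RST_EW.** An independent copy of the same hierarchy per context
(μ₁, μ₂, κ₁, κ₂).  The null model constrains μ₂ = 1 − μ₁ — equivalently,
the average share is 0.5 — with both concentrations left free; since
Beta(2, 2) is symmetric, the induced prior on μ₂ under the null is the same
Beta(2, 2).

**AST/ASC.** Per context, each participant's (target, competitor, decoy)
counts are Multinomial(θ⃗_i) with θ⃗_i ~ Dirichlet(μ⃗κ); μ⃗ ~ Dirichlet(2, 2, 2)
and κ ~ Gamma(0.001, 0.001).  The Beta(2, 2) prior on the RST group means is
the two-category reduction of this Dirichlet(2, 2, 2); both are overridable
through `PriorSpec`.  Inference for AST/ASC is HDI-based (no constrained
null model is defined for it); the group-level AST is the average of the
target components of the two posterior simplex means.

The Gamma prior is parameterized shape–rate.  κ is floored at 1e-6 during
sampling to keep the beta/Dirichlet shapes away from the degenerate
spike-at-the-corners regime.

## Posterior sampling

The individual-level rates are conjugate given the hyperparameters, so the
sampler works on the *collapsed* posterior: the beta-binomial (or
Dirichlet-multinomial) marginal likelihood of the 1–4 free hyperparameters,
sampled by adaptive random-walk Metropolis on an unconstrained scale —
logit for means, log for concentrations, additive log-ratio for simplex
means, each with its Jacobian.  Proposal scale follows Robbins–Monro tuning
toward 30% acceptance and the proposal covariance is matched to the warmup
history (Haario-style); adaptation freezes at the end of warmup.
Individual rates are then completed *exactly* from their conjugate
conditionals (Beta or Dirichlet) for every kept draw, so the retained joint
draws are exact draws from the full hierarchical posterior, not an
approximation to it.

Defaults mirror common practice for these models: 3 chains × 1500
iterations with 500 warmup, retaining 1000 draws per chain.  Because one
Metropolis iteration costs a single vectorized likelihood evaluation, the
sampler inserts 8 Metropolis steps between retained draws (`thin = 8`),
which brings the retained draws close to independence; the
`SamplerConfig.reduced()` preset (3 × 500 kept, thin 4, 300 warmup) is used
for large simulation sweeps.  Convergence is monitored with rank-normalized
split-R̂ (via arviz) on every free parameter, threshold 1.01; exceedances
attach a warning to the result rather than failing, except in the CLI `fit`
command where they set a dedicated exit code.  Chains are initialized at
moment-based estimates jittered per chain; per-chain RNG seeds derive
deterministically from the master seed.

## Marginal likelihoods and Bayes factors

Marginal likelihoods use the iterative optimal-bridge estimator: a
multivariate-normal proposal is moment-matched to the first half of the
posterior draws, the second half enters the Meng–Wong fixed point together
with an equal number of proposal draws, and the iteration (run entirely in
log space) stops when the relative change falls below 1e-10 or after 1000
iterations (failure raises an error carrying the iterate trace; a singular
proposal covariance is ridge-regularized with a warning).  The reported
error is the iid approximation of the relative-MSE formula; it ignores
residual autocorrelation in the MCMC draws, which thinning keeps small.

Bridging happens over the collapsed hyperparameter posterior.  Because the
individual rates integrate out in closed form, the normalizing constant of
the collapsed posterior *is* the marginal likelihood of the full hierarchy,
and a 1–4-dimensional bridge is far more accurate than one over the full
~60–110-dimensional joint.  On conjugate test problems with 10,000 draws
the estimator is within 0.01 nats of the closed form, and the full
sample-then-bridge pipeline agrees with dense-grid quadrature of a small
hierarchy to better than 0.05 nats (see the test suite).

BF₁₀ = exp(log ml_alt − log ml_null); decisions use the conventional
thresholds BF₁₀ ≥ 3 (support for an effect) and ≤ 1/3 (support for the
null), configurable.  HDIs are shortest sorted windows (valid for the
unimodal posteriors produced here, cross-checked against arviz), requiring
at least 100 draws.

## Synthetic data generator

`GeneratorConfig` defaults encode the bias-study conditions: 55
participants, κ = 5, up to n_max = 60 target+competitor trials per context,
and a per-participant sample-size gap drawn from a truncated normal with SD
5 on [0, n_max − 1] (rounded; guaranteeing at least one trial in the
depleted context, which is context 2 by default and switchable).  Scenarios:
*null_true* uses mirror rates μ₁ = p, μ₂ = 1 − p so the average share is
exactly 0.5 while each context can sit far from 0.5 — the regime where the
collapsed measure is most biased; *alternative_true* sets μ₁ = μ₂ = p ≠ 0.5.

The generator emulates role-level binary-core choices only: no decoy
choices, no trial-order or learning effects, no latent participant classes,
and independence across contexts given the group parameters.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data complications.

`run_study` fits both RST measures (null + alternative each) to the
*identical* dataset per replicate — required for the paired UW-vs-EW
comparison — records log BF₁₀, HDIs, decisions and the frequentist t-test
arm, and continues past individual fit failures (recorded per cell).  The
default test-suite scale is 10 replicates at imbalance levels {0, 20, 40}
with the reduced MCMC preset, which reproduces the qualitative bias
pattern; the full 59-level × 100-replicate grid is available through the
same interface (`contextfx simulate`) and completes in hours rather than
minutes.  Under the true null with 55 participants the equal-weights
measure's mean log BF₁₀ is *negative* (evidence accumulates for the null,
BF₀₁ ≈ 5 at these sizes); "unbiased" here means it never drifts toward the
alternative as the imbalance grows, in contrast to the collapsed measure's
monotone climb.

## Correlations

Pairs of per-participant effect values are modeled as bivariate normal;
priors are Normal(0, 100) on means, half-normal(10) on SDs, uniform on the
correlation ρ over (−1, 1), sampled on (means, log SDs, atanh ρ).  Inputs
are raw per-participant proportions by default (keeping the analysis
self-contained); externally supplied values such as posterior means can be
passed instead.  Degenerate inputs (n < 3, a zero-variance margin) raise;
exact linear dependence makes the likelihood unbounded as ρ → 1, in which
case the chains drift up the ridge and the posterior mass piles at the
boundary — reported as-is.

## Known limitations

- Random-walk Metropolis would scale poorly past ~10 free hyperparameters;
  it is adequate here precisely because conjugate collapsing removes the
  individual-level dimensions.
- The bridge error estimate is approximate (iid assumption).
- The baseline-adjusted RST variant used in designs with a binary baseline
  condition is out of scope, as are stimulus construction and
  decoy-placement design.
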