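"""Synthetic two-triplet choice data and the RST bias study.

The generator emulates a population of participants whose per-context target
rates are drawn from a beta distribution (mean ``mu_s``, concentration
``kappa``), who each contribute up to ``n_max`` target-or-competitor choices
per context.  A sample-size *imbalance* is induced by depleting one context:
each participant's number of trials in the depleted context is ``n_max``
minus an integer drawn from a truncated normal (mean ``delta_mean``,
SD ``delta_sd``, support ``[0, n_max - 1]``), so at least one trial always
remains.  Defaults (55 participants, ``kappa = 5``, ``n_max = 60``,
``delta_sd = 5``) are the study conditions of the bias simulation this
package implements.

The study runner fits the null and alternative hierarchies for both RST
measures on identical datasets, computes bridge-sampling Bayes factors, and
(alongside) the conventional one-sample t tests — exposing the bias of the
collapsed-counts RST_UW measure under sample-size imbalance and the
robustness of RST_EW.

Scenario encoding: ``null_true`` uses mirror rates ``mu_1 = p``,
``mu_2 = 1 - p`` so the average share is exactly 0.5 (no IIA violation even
though each context deviates from 0.5); ``alternative_true`` uses
``mu_1 = mu_2 = p != 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .choice_data import ChoiceTrial, ContextCounts
from .evidence import rst_evidence
from .hierarchical import PriorSpec, SamplerConfig
from .measures import DegenerateSampleError, rst_t_test

__all__ = ["GeneratorConfig", "SimulatedDataset", "StudyResult",
           "generate_dataset", "run_study"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generative settings for one synthetic dataset."""

    n_participants: int = 55
    mu_1: float = 0.5
    mu_2: float = 0.5
    kappa: float = 5.0
    n_max: int = 60
    delta_mean: int = 0
    delta_sd: float = 5.0
    seed: int = 0
    deplete_context: int = 2  # which context loses trials (1 or 2)

    def __post_init__(self) -> None:
        if not (0 < self.mu_1 < 1 and 0 < self.mu_2 < 1):
            raise ValueError("group means must lie in (0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 <= self.delta_mean <= self.n_max - 1:
            raise ValueError("delta_mean must be in [0, n_max - 1]")
        if self.deplete_context not in (1, 2):
            raise ValueError("deplete_context must be 1 or 2")


@dataclass(frozen=True)
class SimulatedDataset:
    """Per-participant target counts ``y`` and totals ``N``, shape ``(n, 2)``."""

    y: np.ndarray
    N: np.ndarray
    theta: np.ndarray
    config: GeneratorConfig

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts collapsed over contexts (input to the RST_UW model)."""
        return self.y.sum(axis=1), self.N.sum(axis=1)

    def to_counts(self, effect: str = "other") -> dict[tuple[str, str], ContextCounts]:
        out = {}
        for i in range(self.config.n_participants):
            out[(f"p{i + 1:03d}", effect)] = ContextCounts(
                n_t_C1=int(self.y[i, 0]), n_c_C1=int(self.N[i, 0] - self.y[i, 0]),
                n_d_C1=0,
                n_t_C2=int(self.y[i, 1]), n_c_C2=int(self.N[i, 1] - self.y[i, 1]),
                n_d_C2=0)
        return out

    def to_trials(self, effect: str = "other") -> list[ChoiceTrial]:
        trials = []
        for (pid, eff), c in self.to_counts(effect).items():
            for ctx, n_t, n_c in (("C1", c.n_t_C1, c.n_c_C1),
                                  ("C2", c.n_t_C2, c.n_c_C2)):
                trials += [ChoiceTrial(pid, eff, ctx, "target")] * n_t
                trials += [ChoiceTrial(pid, eff, ctx, "competitor")] * n_c
        return trials


def _truncated_normal_int(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, int(round(mean)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    d = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(d), lo, hi).astype(int)


def generate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Draw one synthetic dataset under ``config``.

    For participant ``i`` and context ``s``: the rate
    ``theta_is ~ Beta(mu_s * kappa, (1 - mu_s) * kappa)``; the full context
    keeps ``n_max`` trials while the depleted context keeps ``n_max - d_i``
    with ``d_i`` a rounded truncated normal on ``[0, n_max - 1]``; the target
    count is ``Binomial(N_is, theta_is)`` and the competitor count the rest.
    Decoys never occur (the generator emulates RST-style binary cores).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mus = np.array([config.mu_1, config.mu_2])
    theta = rng.beta(mus * config.kappa, (1 - mus) * config.kappa, size=(n, 2))
    d = _truncated_normal_int(rng, config.delta_mean, config.delta_sd,
                              0, config.n_max - 1, n)
    N = np.full((n, 2), config.n_max, dtype=int)
    N[:, config.deplete_context - 1] -= d
    y = rng.binomial(N, theta)
    return SimulatedDataset(y=y, N=N, theta=theta, config=config)


@dataclass
class StudyResult:
    """Per-dataset Bayes factors (and t tests) across imbalance levels."""

    records: pd.DataFrame
    scenario: str
    effect_level: float
    seed: int

    def summary(self, confidence: float = 0.95) -> pd.DataFrame:
        """Mean log BF10 per (imbalance level, measure) with a t-based CI."""
        rows = []
        for (level, measure), grp in self.records.groupby(["delta_mean",
                                                           "measure_kind"]):
            vals = grp["log_bf10"].dropna().to_numpy()
            mean = vals.mean() if vals.size else np.nan
            if vals.size > 1 and np.ptp(vals) > 0:
                lo, hi = stats.t.interval(confidence, vals.size - 1, loc=mean,
                                          scale=stats.sem(vals))
            else:
                lo = hi = mean
            rows.append({"delta_mean": level, "measure_kind": measure,
                         "n_datasets": vals.size, "mean_log_bf10": mean,
                         "ci_lo": lo, "ci_hi": hi,
                         "frac_supports_alternative":
                             (grp["decision"] == "supports_alternative").mean()})
        return pd.DataFrame(rows)


def _scenario_means(scenario: str, effect_level: float) -> tuple[float, float]:
    if scenario == "null_true":
        return effect_level, 1.0 - effect_level
    if scenario == "alternative_true":
        return effect_level, effect_level
    raise ValueError(f"unknown scenario {scenario!r}")


def run_study(levels, reps: int, scenario: str = "null_true",
              effect_level: float = 0.6,
              generator: GeneratorConfig | None = None,
              priors: PriorSpec | None = None,
              config: SamplerConfig | None = None,
              seed: int = 0, bf_threshold: float = 3.0,
              t_tests: bool = True) -> StudyResult:
    """Run the bias study over sample-size-imbalance levels.

    For each level in ``levels`` and each of ``reps`` datasets, both RST
    measures are fit (null + alternative hierarchies) to the *identical*
    dataset, giving paired bridge-sampling log Bayes factors; the
    conventional t tests run alongside.  Individual fit failures are recorded
    (``error`` column) and the study continues.

    ``config`` defaults to :meth:`SamplerConfig.reduced`, sized for sweeps;
    pass ``SamplerConfig()`` for the full 3 x (500 + 1000) schedule.
    """
    config = config or SamplerConfig.reduced()
    template = generator or GeneratorConfig()
    mu_1, mu_2 = _scenario_means(scenario, effect_level)
    levels = list(levels)
    seed_grid = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=(len(levels), reps, 3))

    rows = []
    for li, level in enumerate(levels):
        for rep in range(reps):
            gen = replace(template, mu_1=mu_1, mu_2=mu_2, delta_mean=int(level),
                          seed=int(seed_grid[li, rep, 0]))
            ds = generate_dataset(gen)
            data = {"rst_uw": ds.pooled(), "rst_ew": (ds.y, ds.N)}
            for mi, measure in enumerate(("rst_uw", "rst_ew")):
                y, N = data[measure]
                row = {"delta_mean": level, "dataset_index": rep,
                       "measure_kind": measure, "scenario": scenario,
                       "effect_level": effect_level}
                try:
                    ev = rst_evidence(y, N, measure=measure, priors=priors,
                                      config=config,
                                      seed=int(seed_grid[li, rep, 1 + mi]),
                                      bf_threshold=bf_threshold)
                    row.update(log_bf10=np.log(ev.bf10), bf10=ev.bf10,
                               hdi_lo=ev.hdi[0], hdi_hi=ev.hdi[1],
                               decision=ev.decision_bf,
                               decision_hdi=ev.decision_hdi,
                               rhat_alt=ev.diagnostics["rhat_alt"],
                               rhat_null=ev.diagnostics["rhat_null"],
                               error="")
                except Exception as err:  # keep the sweep alive
                    row.update(log_bf10=np.nan, bf10=np.nan,
                               hdi_lo=np.nan, hdi_hi=np.nan,
                               decision="fit_failed", decision_hdi="fit_failed",
                               rhat_alt=np.nan, rhat_null=np.nan,
                               error=f"{type(err).__name__}: {err}")
                if t_tests:
                    if measure == "rst_uw":
                        yy, NN = data[measure]
                        vals = yy / NN
                    else:
                        vals = 0.5 * (ds.y[:, 0] / ds.N[:, 0]
                                      + ds.y[:, 1] / ds.N[:, 1])
                    try:
                        tt = rst_t_test(vals, null_value=0.5)
                        row.update(t_stat=tt.statistic, t_p=tt.p_value)
                    except DegenerateSampleError:
                        row.update(t_stat=np.nan, t_p=np.nan)
                rows.append(row)
    records = pd.DataFrame(rows)
    return StudyResult(records=records, scenario=scenario,
                       effect_level=effect_level, seed=seed)
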