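"""Descriptive choice-share measures for two-triplet context-effect designs.

Four measures are provided, all defined on the six per-participant choice
frequencies (target/competitor/decoy in contexts C1 and C2):

* ``rst_uw`` — relative choice share of the target with *unequal weights*:
  the target count collapsed over both contexts divided by the collapsed
  target+competitor count.  Equivalent to a weighted average of the two
  within-context target shares, with the context sample sizes as weights.
* ``rst_ew`` — relative choice share with *equal weights*: the plain average
  of the two within-context target shares.  Robust to unequal numbers of
  target+competitor choices across contexts.
* ``absolute_shares`` — the absolute choice shares of the target (AST) and
  competitor (ASC): each option's share of *all three* options' choices,
  averaged over contexts.  Values above 0.5 flag regularity violations
  (AST > 0.5: attraction effect; ASC > 0.5: its reversal).
* ``rst_t_test`` — the conventional one-sample t test of mean RST against a
  null value (typically 0.5), kept for comparability with prior literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .choice_data import ContextCounts


class UndefinedMeasureError(ValueError):
    """The requested measure is 0/0 on these counts."""


class DegenerateSampleError(ValueError):
    """A sample statistic is undefined (n < 2 or zero variance)."""


@dataclass(frozen=True)
class MeasureResult:
    """A choice-share value plus its two within-context components."""

    value: float
    within_set_values: tuple[float, float]
    measure_kind: str


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    sidedness: str


def rst_uw(counts: ContextCounts) -> MeasureResult:
    """Relative choice share of the target, unequal weights (collapsed counts)."""
    num = counts.n_t_C1 + counts.n_t_C2
    den = num + counts.n_c_C1 + counts.n_c_C2
    if den == 0:
        raise UndefinedMeasureError("no target or competitor choices in either context")
    t1, t2 = counts.context_totals()
    within = (
        counts.n_t_C1 / t1 if t1 else np.nan,
        counts.n_t_C2 / t2 if t2 else np.nan,
    )
    return MeasureResult(value=num / den, within_set_values=within, measure_kind="RST_UW")


def rst_ew(counts: ContextCounts) -> MeasureResult:
    """Relative choice share of the target, equal weights (mean of within-context shares)."""
    t1, t2 = counts.context_totals()
    if t1 == 0 or t2 == 0:
        raise UndefinedMeasureError("a context has no target or competitor choices")
    within = (counts.n_t_C1 / t1, counts.n_t_C2 / t2)
    return MeasureResult(value=0.5 * (within[0] + within[1]),
                         within_set_values=within, measure_kind="RST_EW")


def absolute_shares(counts: ContextCounts) -> tuple[MeasureResult, MeasureResult]:
    """Absolute choice shares of the target (AST) and competitor (ASC).

    Each is the option's share of all choices in a context (decoys included),
    averaged with equal weight over the two contexts.  AST + ASC <= 1, with
    equality only when the decoy is never chosen.
    """
    t1, t2 = counts.context_totals(include_decoy=True)
    if t1 == 0 or t2 == 0:
        raise UndefinedMeasureError("a context has no choices at all")
    ast_within = (counts.n_t_C1 / t1, counts.n_t_C2 / t2)
    asc_within = (counts.n_c_C1 / t1, counts.n_c_C2 / t2)
    ast = MeasureResult(value=0.5 * sum(ast_within), within_set_values=ast_within,
                        measure_kind="AST")
    asc = MeasureResult(value=0.5 * sum(asc_within), within_set_values=asc_within,
                        measure_kind="ASC")
    return ast, asc


def rst_t_test(values, null_value: float = 0.5,
               sidedness: str = "two_sided") -> TTestResult:
    """One-sample t test of mean choice share against ``null_value``.

    ``sidedness`` is ``"two_sided"`` or ``"greater"`` (H1: mean > null).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError(f"need at least 2 values, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("zero sample variance")
    alternative = {"two_sided": "two-sided", "greater": "greater"}[sidedness]
    res = stats.ttest_1samp(x, popmean=null_value, alternative=alternative)
    return TTestResult(statistic=float(res.statistic), df=int(x.size - 1),
                       p_value=float(res.pvalue), sidedness=sidedness)
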