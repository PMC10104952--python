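"""Reading, validation and aggregation of trial-level choice data.

Two-triplet context-effect experiments present the same pair of core options
inside two three-option sets ("contexts" C1 and C2) that differ only in the
third option.  Every trial therefore reduces to which *role* was chosen —
target, competitor, or decoy — in which context.  This module turns long-format
trial tables into the per-participant count structures that the measures and
models operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("target", "competitor", "decoy")
CONTEXTS = ("C1", "C2")
EFFECTS = ("attraction", "similarity", "compromise", "other")

REQUIRED_COLUMNS = ("participant_id", "effect", "context", "chosen_role")

COUNT_COLUMNS = ("n_t_C1", "n_c_C1", "n_d_C1", "n_t_C2", "n_c_C2", "n_d_C2")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row carries an unknown categorical label."""


@dataclass(frozen=True)
class ChoiceTrial:
    """One choice trial: who chose which role in which context."""

    participant_id: str
    effect: str
    context: str
    chosen_role: str

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect label {self.effect!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context label {self.context!r}")
        if self.chosen_role not in ROLES:
            raise ValidationError(f"unknown role label {self.chosen_role!r}")


@dataclass(frozen=True)
class ContextCounts:
    """Choice frequencies of target/competitor/decoy in each of two contexts."""

    n_t_C1: int
    n_c_C1: int
    n_d_C1: int
    n_t_C2: int
    n_c_C2: int
    n_d_C2: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{f.name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return (self.n_t_C1 + self.n_c_C1 + self.n_d_C1
                + self.n_t_C2 + self.n_c_C2 + self.n_d_C2)

    def context_totals(self, include_decoy: bool = False) -> tuple[int, int]:
        """Target+competitor totals per context (optionally with decoys)."""
        t1 = self.n_t_C1 + self.n_c_C1 + (self.n_d_C1 if include_decoy else 0)
        t2 = self.n_t_C2 + self.n_c_C2 + (self.n_d_C2 if include_decoy else 0)
        return t1, t2

    @property
    def supports_rst(self) -> bool:
        """At least one target-or-competitor choice in each context.

        Without this, a within-context target share is 0/0 and the relative
        choice share of the target is undefined.
        """
        t1, t2 = self.context_totals(include_decoy=False)
        return t1 >= 1 and t2 >= 1


def _column_map(column_map: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {c: c for c in REQUIRED_COLUMNS}
    if column_map:
        mapping.update(column_map)
    return mapping


def read_choice_table(
    path: str | Path,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> list[ChoiceTrial]:
    """Read a long-format trial table into a list of :class:`ChoiceTrial`.

    Parameters
    ----------
    path
        Delimited text file with one row per trial.
    sep
        Field delimiter (``","`` or ``"\\t"``).
    column_map
        Optional mapping from the canonical column names
        (``participant_id``, ``effect``, ``context``, ``chosen_role``)
        to the names actually used in the file.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row holds an unknown role/context/effect label; the message
        names the offending row number.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    mapping = _column_map(column_map)
    for canonical, actual in mapping.items():
        if actual not in frame.columns:
            raise SchemaError(f"missing column {actual!r} (for {canonical!r})")
    trials: list[ChoiceTrial] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        record = {c: getattr(row, mapping[c]) for c in REQUIRED_COLUMNS}
        try:
            trials.append(ChoiceTrial(
                participant_id=str(record["participant_id"]),
                effect=str(record["effect"]),
                context=str(record["context"]),
                chosen_role=str(record["chosen_role"]),
            ))
        except ValidationError as err:
            raise ValidationError(f"row {i + 2}: {err}") from err  # +2: header + 1-based
    return trials


def write_choice_table(trials: Iterable[ChoiceTrial], path: str | Path, sep: str = ",") -> None:
    """Write trials back to delimited text (inverse of :func:`read_choice_table`)."""
    frame = pd.DataFrame(
        [(t.participant_id, t.effect, t.context, t.chosen_role) for t in trials],
        columns=list(REQUIRED_COLUMNS),
    )
    frame.to_csv(path, sep=sep, index=False)


def aggregate_counts(
    trials: Iterable[ChoiceTrial],
) -> dict[tuple[str, str], ContextCounts]:
    """Tally trials into per-(participant, effect) context counts.

    Totals are conserved: the six counts of each cell sum to the number of
    trials in that cell.  Cells with zero trials are simply absent.
    """
    trials = list(trials)
    if not trials:
        logger.warning("aggregate_counts called with no trials; returning empty map")
        return {}
    acc: dict[tuple[str, str], dict[str, int]] = {}
    for t in trials:
        cell = acc.setdefault((t.participant_id, t.effect),
                              {c: 0 for c in COUNT_COLUMNS})
        key = f"n_{t.chosen_role[0]}_{t.context}"
        cell[key] += 1
    return {k: ContextCounts(**v) for k, v in acc.items()}


def counts_to_frame(counts: Mapping[tuple[str, str], ContextCounts]) -> pd.DataFrame:
    """Aggregated counts as a tidy frame, one row per participant x effect."""
    rows = []
    for (pid, effect), c in counts.items():
        rows.append({"participant_id": pid, "effect": effect,
                     **{col: getattr(c, col) for col in COUNT_COLUMNS}})
    return pd.DataFrame(rows, columns=["participant_id", "effect", *COUNT_COLUMNS])


def write_counts_csv(counts: Mapping[tuple[str, str], ContextCounts],
                     path: str | Path, sep: str = ",") -> None:
    counts_to_frame(counts).to_csv(path, sep=sep, index=False)


def read_counts_csv(path: str | Path, sep: str = ",") -> dict[tuple[str, str], ContextCounts]:
    """Read a pre-aggregated count table (one row per participant x effect).

    Expects columns ``participant_id``, ``effect`` and the six count columns
    ``n_t_C1 ... n_d_C2``; decoy columns may be omitted (binary-choice or
    RST-only data) and then default to 0.
    """
    frame = pd.read_csv(path, sep=sep)
    for col in ("participant_id", "effect"):
        if col not in frame.columns:
            raise SchemaError(f"missing column {col!r}")
    for col in ("n_t_C1", "n_c_C1", "n_t_C2", "n_c_C2"):
        if col not in frame.columns:
            raise SchemaError(f"missing column {col!r}")
    out: dict[tuple[str, str], ContextCounts] = {}
    for i, row in frame.iterrows():
        vals = {col: int(row[col]) if col in frame.columns else 0
                for col in COUNT_COLUMNS}
        try:
            out[(str(row["participant_id"]), str(row["effect"]))] = ContextCounts(**vals)
        except ValidationError as err:
            raise ValidationError(f"row {i + 2}: {err}") from err
    return out


def counts_to_model_arrays(counts: Iterable[ContextCounts], measure: str):
    """Stack counts into the array form the hierarchical models consume.

    ``rst_uw``: pooled per-participant ``(y, N)``; ``rst_ew``: per-context
    ``(y, N)`` of shape ``(n, 2)``; ``ast``: a ``(n, 2, 3)`` array of
    (target, competitor, decoy) frequencies per context.
    """
    import numpy as np

    counts = list(counts)
    if measure == "rst_uw":
        y = np.array([c.n_t_C1 + c.n_t_C2 for c in counts], dtype=float)
        n = np.array([c.n_t_C1 + c.n_c_C1 + c.n_t_C2 + c.n_c_C2 for c in counts],
                     dtype=float)
        return y, n
    if measure == "rst_ew":
        y = np.array([[c.n_t_C1, c.n_t_C2] for c in counts], dtype=float)
        n = np.array([[c.n_t_C1 + c.n_c_C1, c.n_t_C2 + c.n_c_C2] for c in counts],
                     dtype=float)
        return y, n
    if measure == "ast":
        return np.array([[[c.n_t_C1, c.n_c_C1, c.n_d_C1],
                          [c.n_t_C2, c.n_c_C2, c.n_d_C2]] for c in counts],
                        dtype=float)
    raise ValueError(f"unknown measure {measure!r}")


def filter_rst_valid(
    counts: Mapping[tuple[str, str], ContextCounts],
) -> tuple[dict[tuple[str, str], ContextCounts], list[tuple[str, str]]]:
    """Drop cells whose within-context target share is undefined (0/0).

    Returns the retained map and the list of excluded keys; exclusions are
    logged so the analyst can see which participants were dropped.
    """
    kept: dict[tuple[str, str], ContextCounts] = {}
    excluded: list[tuple[str, str]] = []
    for key, c in counts.items():
        if c.supports_rst:
            kept[key] = c
        else:
            excluded.append(key)
            logger.info("excluding %s: no target/competitor choice in one context", key)
    return kept, excluded
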