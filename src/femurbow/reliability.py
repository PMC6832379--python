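"""Reliability and group-comparison statistics for radius measurements.

The study's reliability metric is the coefficient of variation (CV) of the
three repeats of each measurement: sample standard deviation (n-1
denominator) divided by the mean.  Group summaries are mean +- sample SD per
part; two-group comparisons use Welch's unequal-variance t-test (the safer
default when no test is named).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ParameterError

__all__ = [
    "PARTS",
    "coefficient_of_variation",
    "aggregate_groups",
    "compare_groups",
    "reliability_report",
    "ReliabilityReport",
]

PARTS = ("whole", "proximal", "middle", "distal")
_PART_COLS = tuple(f"{p}_mm" for p in PARTS)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1) divided by the mean of repeated measurements."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("CV needs at least 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise ParameterError("CV requires a positive mean")
    return float(v.std(ddof=1) / mean)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PART_COLS if c not in table.columns]
    if missing:
        raise ParameterError(f"measurement table lacks radius columns: {missing}")
    if len(table) == 0:
        raise ParameterError("measurement table is empty")
    if (table[list(_PART_COLS)].to_numpy(dtype=float) <= 0).any():
        raise ParameterError("all radii must be positive")
    return table


def aggregate_groups(table: pd.DataFrame, by) -> pd.DataFrame:
    """Per-group sample mean and SD (n-1) of each radius column.

    ``by`` is a column name or list of names.  Groups with a single row get
    a missing SD; empty groups are dropped with a warning.
    """
    _check_table(table)
    if isinstance(by, str):
        by = [by]
    grouped = table.groupby(list(by), dropna=False, observed=True)
    rows = []
    for key, sub in grouped:
        if len(sub) == 0:  # can occur with categorical keys
            warnings.warn(f"group {key!r} is empty; omitted", stacklevel=2)
            continue
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec["n"] = len(sub)
        for part, col in zip(PARTS, _PART_COLS):
            vals = sub[col].to_numpy(dtype=float)
            rec[f"{part}_mean"] = float(vals.mean())
            rec[f"{part}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_groups(a, b):
    """Welch two-sample t-test (two-sided).

    Returns ``(t, p, mean_a, mean_b)``.  Two degenerate-variance groups with
    equal means compare as t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(a.mean()), float(b.mean())
        return float("inf"), 0.0, float(a.mean()), float(b.mean())
    t, p = _stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), float(a.mean()), float(b.mean())


@dataclass(frozen=True)
class ReliabilityReport:
    """CV per (subject, structure, part) plus the min/max/mean summary."""

    per_measurement: pd.DataFrame  # columns: subject, structure, part, n_repeats, cv
    cv_min: float
    cv_max: float
    cv_mean: float

    def summary(self) -> str:
        return (
            f"CV over {len(self.per_measurement)} repeat groups: "
            f"min {self.cv_min:.3f}, max {self.cv_max:.3f}, mean {self.cv_mean:.3f}"
        )


def reliability_report(table: pd.DataFrame) -> ReliabilityReport:
    """CV of the repeats of every (subject, structure) for each of the four
    parts, with the min/max/mean over all such CVs."""
    _check_table(table)
    for col in ("subject", "structure"):
        if col not in table.columns:
            raise ParameterError(f"measurement table lacks a {col!r} column")
    rows = []
    for (subject, structure), sub in table.groupby(["subject", "structure"], observed=True):
        if len(sub) < 2:
            raise ParameterError(
                f"({subject}, {structure}) has {len(sub)} repeat(s); CV needs >= 2"
            )
        for part, col in zip(PARTS, _PART_COLS):
            rows.append(
                {
                    "subject": subject,
                    "structure": structure,
                    "part": part,
                    "n_repeats": len(sub),
                    "cv": coefficient_of_variation(sub[col].to_numpy(dtype=float)),
                }
            )
    per = pd.DataFrame(rows)
    return ReliabilityReport(
        per_measurement=per,
        cv_min=float(per["cv"].min()),
        cv_max=float(per["cv"].max()),
        cv_mean=float(per["cv"].mean()),
    )
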