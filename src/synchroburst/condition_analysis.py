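"""Summary statistics of SBPM across replicates and conditions.

Mirrors how MEA experiments on these cultures are reported: per-condition
mean ± SEM over biological replicates, two-sided Student's t-tests between
pairs of conditions (pooled-variance for independent samples, difference
scores for paired/repeated-measures designs), and developmental time-course
tables of SBPM against days from induction.

No multiple-testing correction is applied — outputs report raw pairwise P
values — and the t-test carries the usual normality assumption, which small
replicate counts cannot verify; treat P values accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burst_detection import DetectorParams, run_detector
from .spike_data import Recording

__all__ = [
    "ConditionSummary",
    "PairwiseComparison",
    "summarize_condition",
    "compare_conditions",
    "timecourse_table",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition SBPM replicates with mean ± SEM.

    ``sem`` is the sample standard deviation (n-1 denominator) over sqrt(n);
    it is ``None`` (undefined) for a single replicate.
    """

    condition: str
    sbpm_values: tuple[float, ...]
    mean: float
    sem: Optional[float]
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    """Two-sided Student's t-test between two conditions."""

    label_a: str
    label_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    paired: bool
    #: True when the statistic is undefined by the usual formula (zero
    #: pooled variance / all-zero paired differences); reported as t=0, p=1.
    degenerate: bool = False


def summarize_condition(
    condition: str, sbpm_values: Sequence[float]
) -> ConditionSummary:
    """Mean ± SEM of SBPM over replicates of one condition."""
    values = tuple(float(v) for v in sbpm_values)
    if not values:
        raise ValueError("at least one SBPM value is required")
    n = len(values)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n >= 2 else None
    return ConditionSummary(condition, values, mean, sem, n)


def compare_conditions(
    a: ConditionSummary, b: ConditionSummary, paired: bool = False
) -> PairwiseComparison:
    """Two-sided Student's t-test between two condition summaries.

    Unpaired uses the pooled-variance (equal-variance) t; paired tests the
    difference scores and requires equal n with aligned replicate order.
    A degenerate case (no variance anywhere) is reported as t=0, p=1 with
    the ``degenerate`` flag set, rather than as an error.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("t-test requires at least two replicates per condition")
    x, y = np.asarray(a.sbpm_values), np.asarray(b.sbpm_values)
    if paired:
        if a.n != b.n:
            raise ValueError("paired comparison requires equal replicate counts")
        diffs = x - y
        dof = float(a.n - 1)
        if np.allclose(diffs.std(ddof=1), 0.0):
            t = 0.0 if np.allclose(diffs, 0.0) else math.inf
            degenerate = True
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_rel(x, y)
            t, p = float(t), float(p)
            degenerate = False
    else:
        dof = float(a.n + b.n - 2)
        if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
            degenerate = True
            t = 0.0 if math.isclose(a.mean, b.mean) else math.inf
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            t, p = float(t), float(p)
            degenerate = False
    return PairwiseComparison(
        a.condition, b.condition, t, dof, p, paired, degenerate
    )


def timecourse_table(
    recordings: Sequence[Recording],
    params: DetectorParams = DetectorParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """SBPM developmental time course: one row per day_from_induction.

    Runs the synchronous-burst detector on every recording, groups by
    ``day_from_induction``, and returns a table of (day, mean_sbpm, sem, n)
    sorted by day, plus the ids of recordings skipped for missing day
    metadata.
    """
    rows = []
    skipped = []
    for rec in recordings:
        if rec.day_from_induction is None:
            skipped.append(rec.recording_id)
            continue
        rows.append((rec.day_from_induction, run_detector(rec, params).sbpm))
    if not rows:
        empty = pd.DataFrame(columns=["day", "mean_sbpm", "sem", "n"])
        return empty, skipped
    df = pd.DataFrame(rows, columns=["day", "sbpm"])
    out = (
        df.groupby("day")["sbpm"]
        .agg(
            mean_sbpm="mean",
            sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="count",
        )
        .reset_index()
        .sort_values("day", ignore_index=True)
    )
    return out, skipped
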