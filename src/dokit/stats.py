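"""Study-level statistics: two-timepoint effect sizes, a-priori sample size
for a two-group RCT via the noncentral t distribution, dropout inflation,
feasibility percentages, and descriptive outcome tables with
last-observation-carried-forward imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Daily ActiGraph outcomes in standard table order.
TABLE_OUTCOMES: tuple[tuple[str, str], ...] = (
    ("sb_min", "SB (minutes per day)"),
    ("sb_pct_of_wear", "Percentage of SB per day (SB per wear time)"),
    ("mean_bout_min", "Duration of SB bouts per day (min)"),
    ("n_bouts", "Number of SB bouts per day"),
    ("n_breaks", "Number of SB breaks per day"),
    ("mvpa_min", "MVPA (minutes per day)"),
    ("light_min", "Light physical activity (minutes per day)"),
    ("vm_counts_total", "VM (counts per day)"),
    ("steps", "Steps per day"),
    ("wear_min", "Wear time (minutes per day)"),
)


@dataclass
class TimepointSummary:
    label: str                       # baseline | week6 | week16
    stats: dict[str, tuple[float, float]]   # outcome -> (mean, sd)
    n: int


@dataclass(frozen=True)
class EffectSize:
    outcome: str
    cohen_d: float
    method: str = "pooled_two_timepoint"


@dataclass
class SampleSizePlan:
    alpha: float
    power: float
    d: float
    n_per_group: int
    n_total: int
    dropout_rate: float = 0.0
    n_recruit_per_group: int | None = None
    n_recruit_total: int | None = None


def cohen_d_two_timepoints(
    mean1: float, sd1: float, mean2: float, sd2: float, outcome: str = ""
) -> EffectSize:
    """Cohen's d between two timepoints with the pooled SD
    sqrt((sd1^2 + sd2^2) / 2); positive d means a reduction from the first
    timepoint. Reported to two decimals."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    d = (mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)
    return EffectSize(outcome=outcome, cohen_d=round(d, 2))


def two_sample_t_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t test at effect size `d` with
    `n_per_group` per arm: df = 2n-2, noncentrality d*sqrt(n/2)."""
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_group_t(
    d: float, alpha: float = 0.05, power: float = 0.80, max_n: int = 10**6
) -> SampleSizePlan:
    """Smallest per-group n whose two-sided two-sample t test reaches the
    target power, by iterating the noncentral t distribution (the standard
    a-priori procedure).

    A normal-approximation start point keeps the search short; correctness
    comes from walking to the exact smallest n afterwards.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = sps.norm.ppf(1 - alpha / 2.0)
    zb = sps.norm.ppf(power)
    approx = 2.0 * ((za + zb) / d) ** 2
    if approx > max_n:
        raise ValueError(f"required n exceeds {max_n} per group for d={d}")
    n = max(2, int(approx) - 10)
    while two_sample_t_power(d, n, alpha) < power:
        n += 1
        if n > max_n:
            raise ValueError(f"required n exceeds {max_n} per group for d={d}")
    while n > 2 and two_sample_t_power(d, n - 1, alpha) >= power:
        n -= 1
    return SampleSizePlan(
        alpha=alpha, power=power, d=d, n_per_group=n, n_total=2 * n
    )


def inflate_for_dropout(plan: SampleSizePlan, dropout_rate: float) -> SampleSizePlan:
    """Recruitment numbers allowing for attrition:
    ceil(n_per_group / (1 - dropout_rate)) per group."""
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout rate must be in [0, 1)")
    per_group = math.ceil(plan.n_per_group / (1.0 - dropout_rate))
    return SampleSizePlan(
        alpha=plan.alpha,
        power=plan.power,
        d=plan.d,
        n_per_group=plan.n_per_group,
        n_total=plan.n_total,
        dropout_rate=dropout_rate,
        n_recruit_per_group=per_group,
        n_recruit_total=2 * per_group,
    )


def feasibility_percent(
    numerator: int, denominator: int, decimals: int = 0
) -> float:
    """100*num/den with half-up rounding to `decimals` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    scale = 10**decimals
    return math.floor(100.0 * numerator / denominator * scale + 0.5) / scale


def locf(
    wide: pd.DataFrame, timepoints: Sequence[str] | None = None
) -> pd.DataFrame:
    """Last observation carried forward across ordered timepoint columns
    (rows = participants). Only fills gaps after an observed value; leading
    missing values stay missing."""
    cols = list(timepoints) if timepoints is not None else list(wide.columns)
    return wide[cols].ffill(axis=1)


def summarize_timepoint(
    label: str, values: Mapping[str, Sequence[float]]
) -> TimepointSummary:
    """Mean/SD per outcome for one timepoint (SD 0 when n == 1)."""
    stats: dict[str, tuple[float, float]] = {}
    n = 0
    for outcome, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[~np.isnan(arr)]
        n = max(n, len(arr))
        mean = float(arr.mean()) if len(arr) else float("nan")
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        stats[outcome] = (mean, sd)
    return TimepointSummary(label=label, stats=stats, n=n)


def cohort_table(
    summaries: Sequence[TimepointSummary],
    outcomes: Sequence[tuple[str, str]] = TABLE_OUTCOMES,
) -> pd.DataFrame:
    """Descriptive outcome table: one row per outcome, one
    ``mean (SD)`` column per timepoint, in standard order."""
    rows = []
    for key, label in outcomes:
        row = {"outcome": label}
        for s in summaries:
            if key in s.stats:
                m, sd = s.stats[key]
                row[f"{s.label}, mean (SD)"] = f"{m:.1f} ({sd:.1f})"
            else:
                row[f"{s.label}, mean (SD)"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
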