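"""Hip-accelerometry processing: epoch counts -> per-day and per-participant
sedentary-behaviour / physical-activity summaries.

The pipeline starts from exported 15-second triaxial epoch counts (raw 30 Hz
to counts conversion is proprietary to the device vendor and out of scope):

1. epochs are aggregated to vector-magnitude counts per minute (cpm);
2. nonwear is flagged as runs of more than 60 consecutive zero-cpm minutes,
   with no allowance for nonzero epochs inside a run;
3. wear minutes are classified with the triaxial vector-magnitude cut-points
   (sedentary <150 cpm, light 150-2689 cpm, MVPA >=2690 cpm);
4. sedentary bouts (>=10 min, no drop time) and breaks are extracted;
5. days with >=10 h wear are valid; participants need >=4 valid days, and all
   valid days are averaged even when more than 7 exist.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EPOCH_SECONDS = 15
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS

# Sasaki triaxial vector-magnitude cut-points (cpm)
SEDENTARY_CPM = 150.0   # below -> sedentary
MVPA_CPM = 2690.0       # at or above -> MVPA

NONWEAR_MIN_RUN = 61    # ">60 consecutive minutes" of zero activity
VALID_DAY_WEAR_MIN = 600
MIN_VALID_DAYS = 4

SEDENTARY, LIGHT, MVPA, NONWEAR = "sedentary", "light", "mvpa", "nonwear"


class EpochGridError(ValueError):
    """Raised when epoch timestamps are not on a clean 15-second grid."""


@dataclass(frozen=True)
class WearInterval:
    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    is_wear: bool

    @property
    def minutes(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(minutes=1))


@dataclass(frozen=True)
class Bout:
    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    duration_min: int


@dataclass
class DayActivitySummary:
    date: Date
    wear_min: int
    sb_min: int
    light_min: int
    mvpa_min: int
    sb_pct_of_wear: float
    n_bouts: int
    mean_bout_min: float
    n_breaks: int
    vm_counts_total: float
    steps: float
    valid: bool

    FIELDS = (
        "date", "wear_min", "sb_min", "light_min", "mvpa_min",
        "sb_pct_of_wear", "n_bouts", "mean_bout_min", "n_breaks",
        "vm_counts_total", "steps", "valid",
    )


@dataclass
class ParticipantAccelSummary:
    """Per-participant means over valid days (Table-style daily outcomes)."""

    n_valid_days: int
    meets_wear_criteria: bool
    sb_min: float = float("nan")
    sb_pct_of_wear: float = float("nan")
    mean_bout_min: float = float("nan")
    n_bouts: float = float("nan")
    n_breaks: float = float("nan")
    mvpa_min: float = float("nan")
    light_min: float = float("nan")
    vm_counts_total: float = float("nan")
    steps: float = float("nan")
    wear_min: float = float("nan")


def read_epoch_csv(path) -> pd.DataFrame:
    """Read an epoch CSV (``timestamp,ax,ay,az``).

    Tolerates a vendor preamble of up to ~10 lines: leading lines are skipped
    until one starting with ``timestamp`` is found.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    for i, line in enumerate(lines[:11]):
        if line.strip().lower().startswith("timestamp"):
            start = i
            break
    else:
        raise ValueError(f"{path}: no 'timestamp' header found in first 11 lines")
    df = pd.read_csv(io.StringIO("".join(lines[start:])))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def epochs_to_minutes(epochs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate 15-s triaxial epochs to vector-magnitude counts per minute.

    Per-epoch VM is sqrt(ax^2+ay^2+az^2); a minute's cpm is the sum of its
    (up to 4) epoch VMs, with partial minutes scaled by 4/(epochs present) to
    keep cpm units.

    Parameters
    ----------
    epochs : DataFrame with columns ``timestamp, ax, ay, az``.

    Returns
    -------
    DataFrame with columns ``minute_start, vm_cpm`` (one row per clock minute
    covered by at least one epoch).
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch input")
    ts = pd.DatetimeIndex(epochs["timestamp"])
    ns = ts.asi8
    off = ns % (EPOCH_SECONDS * 1_000_000_000)
    if off.any():
        bad = ts[np.nonzero(off)[0][0]]
        raise EpochGridError(f"timestamp off 15-second grid: {bad}")
    if len(ns) > 1 and not (np.diff(ns) > 0).all():
        bad = ts[int(np.nonzero(np.diff(ns) <= 0)[0][0]) + 1]
        raise ValueError(f"timestamps not strictly increasing at {bad}")
    counts = epochs[["ax", "ay", "az"]].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative activity counts")
    vm = np.sqrt((counts**2).sum(axis=1))

    minute = ts.floor("min")
    g = pd.DataFrame({"minute_start": minute, "vm": vm}).groupby(
        "minute_start", sort=True
    )["vm"].agg(["sum", "count"])
    vm_cpm = g["sum"] * (EPOCHS_PER_MINUTE / g["count"])
    return pd.DataFrame(
        {"minute_start": g.index, "vm_cpm": vm_cpm.to_numpy()}
    ).reset_index(drop=True)


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    if len(is_zero) == 0:
        return []
    padded = np.concatenate(([False], is_zero, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_nonwear(minutes: pd.DataFrame) -> list[WearInterval]:
    """Flag nonwear: maximal runs of zero cpm of at least 61 minutes.

    A single minute with any activity splits a run — no allowance. Runs of
    exactly 60 zero minutes remain wear. Returns alternating wear/nonwear
    intervals partitioning the recorded span (empty input -> empty list).
    """
    n = len(minutes)
    if n == 0:
        return []
    t0 = pd.Timestamp(minutes["minute_start"].iloc[0])
    one = pd.Timedelta(minutes=1)
    vm = minutes["vm_cpm"].to_numpy(dtype=float)
    nonwear = np.zeros(n, dtype=bool)
    for a, b in _zero_runs(vm == 0):
        if b - a >= NONWEAR_MIN_RUN:
            nonwear[a:b] = True
    out: list[WearInterval] = []
    for a, b in _zero_runs(nonwear):
        out.append(WearInterval(t0 + a * one, t0 + b * one, is_wear=False))
    for a, b in _zero_runs(~nonwear):
        out.append(WearInterval(t0 + a * one, t0 + b * one, is_wear=True))
    out.sort(key=lambda w: w.start)
    return out


def nonwear_mask(minutes: pd.DataFrame) -> np.ndarray:
    """Boolean mask aligned with `minutes`: True where the minute is nonwear."""
    n = len(minutes)
    mask = np.zeros(n, dtype=bool)
    vm = minutes["vm_cpm"].to_numpy(dtype=float)
    for a, b in _zero_runs(vm == 0):
        if b - a >= NONWEAR_MIN_RUN:
            mask[a:b] = True
    return mask


def classify_minute(vm_cpm: float) -> str:
    """Intensity from vector-magnitude cpm via the triaxial cut-points."""
    if vm_cpm < 0:
        raise ValueError(f"negative cpm: {vm_cpm}")
    if vm_cpm < SEDENTARY_CPM:
        return SEDENTARY
    if vm_cpm < MVPA_CPM:
        return LIGHT
    return MVPA


def classify_minutes(minutes: pd.DataFrame) -> pd.DataFrame:
    """Add an ``intensity`` column (nonwear minutes flagged first)."""
    vm = minutes["vm_cpm"].to_numpy(dtype=float)
    if (vm < 0).any():
        raise ValueError("negative cpm")
    mask = nonwear_mask(minutes)
    intensity = np.where(
        vm < SEDENTARY_CPM, SEDENTARY, np.where(vm < MVPA_CPM, LIGHT, MVPA)
    ).astype(object)
    intensity[mask] = NONWEAR
    out = minutes.copy()
    out["intensity"] = intensity
    return out


def detect_bouts(
    day_minutes: pd.DataFrame, min_len: int = 10, drop_time: int = 0
) -> list[Bout]:
    """Sedentary bouts: runs of sedentary wear minutes of at least `min_len`.

    With ``drop_time=0`` (the default, "no drop time") any non-sedentary
    minute terminates a run. With a positive drop time a bout may absorb up
    to `drop_time` interrupting minutes in total but must start and end on a
    sedentary minute.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if drop_time < 0:
        raise ValueError("drop_time must be >= 0")
    n = len(day_minutes)
    if n == 0:
        return []
    t0 = pd.Timestamp(day_minutes["minute_start"].iloc[0])
    one = pd.Timedelta(minutes=1)
    sed = (day_minutes["intensity"].to_numpy() == SEDENTARY)

    bouts: list[Bout] = []
    if drop_time == 0:
        runs = _zero_runs(sed)
    else:
        runs = []
        i = 0
        while i < n:
            if not sed[i]:
                i += 1
                continue
            j, last_sed, dropped = i, i, 0
            while j < n:
                if sed[j]:
                    last_sed = j
                elif dropped + 1 > drop_time or j == i:
                    break
                else:
                    dropped += 1
                j += 1
            runs.append((i, last_sed + 1))
            i = last_sed + 1
    for a, b in runs:
        if b - a >= min_len:
            bouts.append(Bout(t0 + a * one, t0 + b * one, b - a))
    return bouts


def count_breaks(
    bouts: Sequence[Bout],
    day_minutes: pd.DataFrame,
    count_trailing: bool = False,
) -> int:
    """Breaks in sedentary time: bouts followed (before day end) by at least
    one wear, non-sedentary minute.

    Standard daily-bout outputs leave "break" undefined; this definition
    yields breaks = bouts - 1 whenever the day ends inside or immediately
    after the final bout, matching how the two are usually tabulated
    together. ``count_trailing=True`` switches to the alternative convention
    where every bout termination is a break (breaks = bouts).
    """
    if not bouts:
        return 0
    if count_trailing:
        return len(bouts)
    intensity = day_minutes["intensity"].to_numpy()
    t0 = pd.Timestamp(day_minutes["minute_start"].iloc[0])
    one = pd.Timedelta(minutes=1)
    n = len(intensity)
    breaks = 0
    for bout in bouts:
        k = int((bout.end - t0) / one)
        j = k
        while j < n:
            if intensity[j] == SEDENTARY:
                # next sedentary run begins before any activity: with maximal
                # runs this cannot happen immediately, but guard anyway
                break
            if intensity[j] in (LIGHT, MVPA):
                breaks += 1
                break
            j += 1  # nonwear: keep scanning
    return breaks


def summarize_day(
    day_minutes: pd.DataFrame,
    steps: float = float("nan"),
    min_bout_len: int = 10,
) -> DayActivitySummary:
    """Per-day wear, intensity minutes, bout statistics and validity."""
    if len(day_minutes) == 0:
        raise ValueError("empty day")
    if "intensity" not in day_minutes:
        day_minutes = classify_minutes(day_minutes)
    d = pd.Timestamp(day_minutes["minute_start"].iloc[0]).date()
    intensity = day_minutes["intensity"].to_numpy()
    wear = intensity != NONWEAR
    sb = int((intensity == SEDENTARY).sum())
    light = int((intensity == LIGHT).sum())
    mvpa = int((intensity == MVPA).sum())
    wear_min = int(wear.sum())
    bouts = detect_bouts(day_minutes, min_len=min_bout_len)
    breaks = count_breaks(bouts, day_minutes)
    vm_total = float(day_minutes["vm_cpm"].to_numpy()[wear].sum())
    return DayActivitySummary(
        date=d,
        wear_min=wear_min,
        sb_min=sb,
        light_min=light,
        mvpa_min=mvpa,
        sb_pct_of_wear=(100.0 * sb / wear_min) if wear_min > 0 else 0.0,
        n_bouts=len(bouts),
        mean_bout_min=(
            float(np.mean([b.duration_min for b in bouts])) if bouts else 0.0
        ),
        n_breaks=breaks,
        vm_counts_total=vm_total,
        steps=steps,
        valid=wear_min >= VALID_DAY_WEAR_MIN,
    )


def summarize_participant(
    days: Sequence[DayActivitySummary],
) -> ParticipantAccelSummary:
    """Means over valid days only; all valid days are used even when >7."""
    if len(days) == 0:
        raise ValueError("no days")
    valid = [d for d in days if d.valid]
    out = ParticipantAccelSummary(
        n_valid_days=len(valid),
        meets_wear_criteria=len(valid) >= MIN_VALID_DAYS,
    )
    if not valid:
        return out
    for attr in (
        "sb_min", "sb_pct_of_wear", "mean_bout_min", "n_bouts", "n_breaks",
        "mvpa_min", "light_min", "vm_counts_total", "steps", "wear_min",
    ):
        vals = np.asarray([getattr(d, attr) for d in valid], dtype=float)
        vals = vals[~np.isnan(vals)]
        setattr(out, attr, float(vals.mean()) if len(vals) else float("nan"))
    return out


def process_participant(
    epochs: pd.DataFrame,
    steps_by_date: dict[Date, float] | None = None,
) -> tuple[list[DayActivitySummary], ParticipantAccelSummary]:
    """Full per-participant pipeline from an epoch table.

    Days are local midnight-to-midnight; device-reported steps, if supplied,
    are carried through to the day summaries.
    """
    minutes = epochs_to_minutes(epochs)
    minutes["_date"] = pd.DatetimeIndex(minutes["minute_start"]).date
    days: list[DayActivitySummary] = []
    for d, grp in minutes.groupby("_date", sort=True):
        grp = classify_minutes(grp.drop(columns="_date").reset_index(drop=True))
        steps = float("nan")
        if steps_by_date is not None:
            steps = steps_by_date.get(d, float("nan"))
        days.append(summarize_day(grp, steps=steps))
    return days, summarize_participant(days)


def day_summaries_to_csv(days: Iterable[DayActivitySummary], path) -> None:
    rows = [{f: getattr(d, f) for f in DayActivitySummary.FIELDS} for d in days]
    pd.DataFrame(rows, columns=list(DayActivitySummary.FIELDS)).to_csv(
        path, index=False
    )
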