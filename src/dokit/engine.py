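"""Behavioural scoring and Do dispatch.

Three daily variables — physical activity (steps, active minutes), social
opportunity (new places, dwell time in them) and variety (uncommon places,
distance, route dissimilarity, timing shift) — are scored 0-10 against a
participant's own baseline week: each subcomponent is linearly rescaled
between the minimum and maximum recorded during that week (values at or
below the minimum score 0, at or above the maximum score 10) and a
variable's score is the equal-weight mean of its rescaled subcomponents.

A data-driven Do is dispatched when a variable's score has been low
(< 10/3 by default, the sad-face band) on three consecutive days, each of
those days passed the >60% intraday data-coverage gate, fewer than three
Do's have already gone out this ISO week, and an unused data-driven Do for
that variable remains in the catalog. Core Do's selected from the intake
questionnaire are interleaved one per week under the same shared cap.
Daily feedback is a sad/neutral/smiley face per variable in a 14-day
overview.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .catalog import CORE, DATA_DRIVEN, Do

log = logging.getLogger(__name__)

VARIABLES = ("pa", "social", "variety")

LOW_THRESHOLD = 10.0 / 3.0
COVERAGE_GATE = 0.60           # strictly-greater-than gate
CAP_PER_WEEK = 3
LOW_STREAK_DAYS = 3
FACE_BANDS = (10.0 / 3.0, 20.0 / 3.0)
SAD, NEUTRAL, SMILEY = "sad", "neutral", "smiley"

CORE_SCHEDULE = "core_schedule"


def low_score_trigger(variable: str) -> str:
    return f"low_score:{variable}"


class InsufficientBaselineError(ValueError):
    pass


class EngineConfig(BaseModel):
    """Tunable dispatch-engine knobs, loadable from YAML.

    ``low_threshold`` and the face bands default to thirds of the 0-10
    score range so that "low" coincides with the sad face.
    """

    low_threshold: float = Field(default=LOW_THRESHOLD, gt=0, lt=10)
    coverage_gate: float = Field(default=0.60, ge=0, le=1)
    cap_per_week: int = Field(default=3, ge=1)
    streak_days: int = Field(default=3, ge=1)
    face_bands: tuple[float, float] = (10.0 / 3.0, 20.0 / 3.0)
    breaks_count_trailing: bool = False

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def policy(self, catalog: Sequence["Do"], seed: int) -> "DispatchPolicy":
        return DispatchPolicy(
            catalog,
            seed=seed,
            low_threshold=self.low_threshold,
            coverage_gate=self.coverage_gate,
            cap_per_week=self.cap_per_week,
            streak_days=self.streak_days,
        )


@dataclass
class RawDailyVariables:
    """One day's raw subcomponent values plus the data-coverage fraction."""

    date: Date
    coverage: float
    pa: Mapping[str, float]        # steps, active_min
    social: Mapping[str, float]    # n_new_places, dwell_in_new_places_min
    variety: Mapping[str, float]   # n_uncommon_places, distance_km,
    #                                route_dissimilarity, timing_shift


@dataclass
class BaselineProfile:
    """Per-subcomponent (min, max) observed over the baseline week."""

    bounds: dict[str, dict[str, tuple[float, float]]]
    n_days_used: int


@dataclass
class DailyScores:
    date: Date
    pa: float
    social: float
    variety: float
    coverage: float
    faces: dict[str, str] = field(default_factory=dict)

    def score(self, variable: str) -> float:
        return getattr(self, variable)


@dataclass
class DispatchEvent:
    do_id: int
    date: Date
    trigger: str                   # core_schedule | low_score:<variable>
    completed: bool = False


@dataclass(frozen=True)
class IntakeResponse:
    item_id: str
    answer: int                    # ordinal 1-5


def compute_baseline(
    week: Sequence[RawDailyVariables],
    coverage_gate: float = COVERAGE_GATE,
    min_days: int = 3,
) -> BaselineProfile:
    """Per-subcomponent min/max over the 7-day baseline week.

    Days failing the coverage gate are excluded; at least `min_days` passing
    days are required.
    """
    if len(week) != 7:
        raise ValueError(f"baseline week must have exactly 7 days, got {len(week)}")
    days = [d for d in week if d.coverage > coverage_gate]
    if len(days) < min_days:
        raise InsufficientBaselineError(
            f"insufficient baseline: only {len(days)} of 7 days pass the "
            f">{coverage_gate:.0%} coverage gate (need {min_days})"
        )
    bounds: dict[str, dict[str, tuple[float, float]]] = {}
    for var in VARIABLES:
        subs: dict[str, tuple[float, float]] = {}
        for name in getattr(days[0], var):
            vals = [float(getattr(d, var)[name]) for d in days]
            subs[name] = (min(vals), max(vals))
        bounds[var] = subs
    return BaselineProfile(bounds=bounds, n_days_used=len(days))


def rescale(value: float, min_value: float, max_value: float) -> float:
    """Linear 0-10 rescale against baseline bounds.

    Values at or below the minimum map to 0, at or above the maximum to 10.
    A degenerate baseline (min == max) maps every value to the neutral 5.
    """
    if min_value > max_value:
        raise ValueError(f"min {min_value} > max {max_value}")
    if min_value == max_value:
        return 5.0
    if value <= min_value:
        return 0.0
    if value >= max_value:
        return 10.0
    return 10.0 * (value - min_value) / (max_value - min_value)


def face_for(score: float, bands: tuple[float, float] = FACE_BANDS) -> str:
    if score < bands[0]:
        return SAD
    if score < bands[1]:
        return NEUTRAL
    return SMILEY


def daily_scores(
    raw: RawDailyVariables,
    baseline: BaselineProfile,
    face_bands: tuple[float, float] = FACE_BANDS,
) -> DailyScores:
    """Score one day against the baseline profile (equal-weight means)."""
    out = {}
    for var in VARIABLES:
        subs = baseline.bounds[var]
        vals = [
            rescale(float(getattr(raw, var)[name]), lo, hi)
            for name, (lo, hi) in subs.items()
        ]
        out[var] = float(np.mean(vals)) if vals else 5.0
    scores = DailyScores(
        date=raw.date,
        pa=out["pa"],
        social=out["social"],
        variety=out["variety"],
        coverage=raw.coverage,
    )
    scores.faces = {v: face_for(scores.score(v), face_bands) for v in VARIABLES}
    return scores


def _iso_week(day: Date) -> tuple[int, int]:
    iso = day.isocalendar()
    return (iso[0], iso[1])


def select_core_dos(
    intake: Sequence[IntakeResponse], catalog: Sequence[Do]
) -> list[Do]:
    """Core Do's whose activation rules match the intake answers, in
    priority order. An empty intake activates nothing."""
    answers = {r.item_id: r.answer for r in intake}
    selected = [
        d
        for d in catalog
        if d.kind == CORE
        and any(
            answers.get(rule["item"], 0) >= rule["min_answer"]
            for rule in d.activation_rules
        )
    ]
    return sorted(selected, key=lambda d: (d.priority, d.do_id))


class DispatchPolicy:
    """Stateful dispatch policy for one participant.

    Holds the participant's seeded shuffle of the data-driven catalog (so
    "individualised" Do sequences differ between participants but runs are
    reproducible), the set of already-sent Do ids, and the weekly-cap and
    consecutive-low-day bookkeeping. A dispatched data-driven Do resets the
    low-day counter for its variable.
    """

    def __init__(
        self,
        catalog: Sequence[Do],
        seed: int,
        low_threshold: float = LOW_THRESHOLD,
        coverage_gate: float = COVERAGE_GATE,
        cap_per_week: int = CAP_PER_WEEK,
        streak_days: int = LOW_STREAK_DAYS,
    ):
        self.catalog = list(catalog)
        self.low_threshold = low_threshold
        self.coverage_gate = coverage_gate
        self.cap_per_week = cap_per_week
        self.streak_days = streak_days
        rng = np.random.default_rng(seed)
        self.queues: dict[str, list[int]] = {}
        for var in VARIABLES:
            ids = [d.do_id for d in self.catalog if d.kind == DATA_DRIVEN and d.target == var]
            rng.shuffle(ids)
            self.queues[var] = ids
        self.used: set[int] = set()
        self.log: list[DispatchEvent] = []
        self._last_dd_date: dict[str, Date] = {}

    # -- bookkeeping -------------------------------------------------------
    def _week_count(self, day: Date) -> int:
        wk = _iso_week(day)
        return sum(1 for e in self.log if _iso_week(e.date) == wk)

    def record(self, event: DispatchEvent) -> None:
        self.log.append(event)
        self.used.add(event.do_id)
        if event.trigger != CORE_SCHEDULE:
            var = event.trigger.split(":", 1)[1]
            self._last_dd_date[var] = event.date

    # -- core schedule -----------------------------------------------------
    def dispatch_core(self, do: Do, day: Date) -> DispatchEvent | None:
        """Send a scheduled core Do if the weekly cap allows it."""
        if do.do_id in self.used:
            return None
        if self._week_count(day) >= self.cap_per_week:
            log.info("cap hit: core Do %s not sent on %s", do.do_id, day)
            return None
        event = DispatchEvent(do_id=do.do_id, date=day, trigger=CORE_SCHEDULE)
        self.record(event)
        return event

    # -- data-driven trigger ----------------------------------------------
    def check_dispatch(
        self, history: Sequence[DailyScores], today: Date
    ) -> DispatchEvent | None:
        """Evaluate the 3-consecutive-low-day rule for `today`.

        `history` must cover at least the `streak_days` days ending today.
        Returns the dispatched event, or None with the gate decision logged.
        """
        k = self.streak_days
        if len(history) < k:
            return None
        window = history[-k:]
        if window[-1].date != today:
            raise ValueError("history must end at `today`")
        candidates = []
        for var in VARIABLES:
            scores = [d.score(var) for d in window]
            if not all(s < self.low_threshold for s in scores):
                continue
            if not all(d.coverage > self.coverage_gate for d in window):
                log.info("coverage gate blocks %s dispatch on %s", var, today)
                continue
            last = self._last_dd_date.get(var)
            if last is not None and (today - last).days < k:
                continue  # streak reset by a recent dispatch for this variable
            candidates.append((float(np.mean(scores)), VARIABLES.index(var), var))
        if not candidates:
            return None
        if self._week_count(today) >= self.cap_per_week:
            log.info("weekly cap (%d) hit on %s", self.cap_per_week, today)
            return None
        candidates.sort()
        var = candidates[0][2]
        queue = [i for i in self.queues[var] if i not in self.used]
        if not queue:
            log.warning("data-driven catalog exhausted for %s on %s", var, today)
            return None
        event = DispatchEvent(
            do_id=queue[0], date=today, trigger=low_score_trigger(var)
        )
        self.record(event)
        return event


def check_dispatch(
    history: Sequence[DailyScores],
    log_: Sequence[DispatchEvent],
    catalog: Sequence[Do],
    today: Date,
    low_threshold: float = LOW_THRESHOLD,
    seed: int = 0,
) -> DispatchEvent | None:
    """One-shot functional wrapper around :class:`DispatchPolicy`.

    Rebuilds policy state from an explicit event log; suited to replaying or
    auditing. Long-running use should hold a DispatchPolicy instead.
    """
    policy = DispatchPolicy(catalog, seed=seed, low_threshold=low_threshold)
    for e in log_:
        policy.record(e)
    return policy.check_dispatch(history, today)


def adherence(events: Sequence[DispatchEvent]) -> float | None:
    """Percent of dispatched Do's marked completed (one decimal, half-up);
    None when nothing was dispatched."""
    n = len(events)
    if n == 0:
        return None
    done = sum(1 for e in events if e.completed)
    return math.floor(1000.0 * done / n + 0.5) / 10.0


def fourteen_day_overview(
    scores: Sequence[DailyScores],
    face_bands: tuple[float, float] = FACE_BANDS,
    coverage_gate: float = COVERAGE_GATE,
) -> dict[str, list[str]]:
    """3 x <=14 grid of faces for the app's 14-day overview.

    Low-coverage days render blank (empty string).
    """
    window = list(scores)[-14:]
    grid: dict[str, list[str]] = {v: [] for v in VARIABLES}
    for day in window:
        for var in VARIABLES:
            if day.coverage > coverage_gate:
                grid[var].append(face_for(day.score(var), face_bands))
            else:
                grid[var].append("")
    return grid
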