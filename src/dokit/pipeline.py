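"""End-to-end orchestration: simulate -> score -> dispatch -> measure ->
report.

`run_participant` couples the generator to the dispatch engine in a closed
loop: day by day the simulator emits streams, the engine scores them against
the participant's baseline week and may dispatch a Do, and completed Do's
feed back into the next day's sitting time. `run_cohort` assembles the
study-level outputs: descriptive outcome tables at 0/6/16 weeks (with
last-observation-carried-forward imputation for missed follow-ups), effect
sizes, an RCT sample-size plan, and adherence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import accel, gps, stats
from .catalog import Do, default_catalog
from .engine import (
    DailyScores,
    DispatchEvent,
    DispatchPolicy,
    InsufficientBaselineError,
    RawDailyVariables,
    compute_baseline,
    daily_scores,
    select_core_dos,
)
from .engine import adherence as adherence_pct
from .simulate import (
    CohortConfig,
    ParticipantProfile,
    ParticipantSimulator,
    generate_intake,
    sample_profile,
)

log = logging.getLogger(__name__)


@dataclass
class ParticipantResult:
    profile: ParticipantProfile
    days: list                      # DayRecord per simulated day
    scores: list[DailyScores]
    events: list[DispatchEvent]
    completed: int
    accel_summaries: dict[str, accel.ParticipantAccelSummary]
    dropped_week6: bool
    dropped_week16: bool
    baseline_failed: bool = False

    @property
    def n_dispatched(self) -> int:
        return len(self.events)


@dataclass
class CohortResult:
    participants: list[ParticipantResult]
    summaries: list[stats.TimepointSummary]
    effect_sizes: dict[str, stats.EffectSize]
    plan: stats.SampleSizePlan | None
    adherence: float | None
    table: pd.DataFrame


def run_participant(
    profile: ParticipantProfile,
    config: CohortConfig,
    catalog: list[Do] | None = None,
    score_from_gps: bool = False,
) -> ParticipantResult:
    """Simulate one participant through the full program, closed loop."""
    catalog = catalog if catalog is not None else default_catalog()
    sim = ParticipantSimulator(profile)
    aux = np.random.default_rng([profile.seed, 11])  # intake/completion/dropout
    intake = generate_intake(profile, aux)
    core_queue = select_core_dos(intake, catalog)
    policy = DispatchPolicy(catalog, seed=profile.seed)

    windows = config.assessment_windows()
    epoch_days: set[int] = (
        set().union(*windows.values()) if config.assessment_epochs else set()
    )
    dispatch_days = set(config.dispatch_days)

    registry = gps.PlaceRegistry()
    baseline_visits: list[list[gps.Visit]] = []

    days, history = [], []
    baseline = None
    baseline_failed = False
    raw_week: list[RawDailyVariables] = []
    completed = 0

    for i in range(config.n_days):
        day = config.start_date + timedelta(days=i)
        rec = sim.simulate_day(
            day,
            completed_dos=completed,
            with_epochs=i in epoch_days,
            with_gps=score_from_gps,
        )
        days.append(rec)
        raw = rec.raw
        if score_from_gps:
            feats, visits = gps.daily_mobility(
                day,
                rec.gps,
                registry,
                baseline_visits if i >= config.baseline_days else None,
            )
            if i < config.baseline_days:
                baseline_visits.append(visits)
            raw = RawDailyVariables(
                date=day,
                coverage=rec.coverage,
                pa=raw.pa,  # device stream: steps and active minutes
                social={
                    "n_new_places": feats.n_new_places,
                    "dwell_in_new_places_min": feats.dwell_in_new_places_min,
                },
                variety={
                    "n_uncommon_places": feats.n_uncommon_places,
                    "distance_km": feats.distance_km,
                    "route_dissimilarity": feats.route_dissimilarity,
                    "timing_shift": feats.timing_shift,
                },
            )
        if i < config.baseline_days:
            raw_week.append(raw)
            if i == config.baseline_days - 1:
                try:
                    baseline = compute_baseline(raw_week)
                except InsufficientBaselineError as exc:
                    log.warning("participant %d: %s", profile.pid, exc)
                    baseline_failed = True
            continue

        if baseline is None:
            continue
        history.append(daily_scores(raw, baseline))
        if i not in dispatch_days:
            continue
        if day.weekday() in (0, 3) and core_queue:  # core slots (Mon, Thu)
            event = policy.dispatch_core(core_queue[0], day)
            if event is not None:
                core_queue.pop(0)
                event.completed = bool(aux.random() < config.completion_prob)
                completed += event.completed
        event = policy.check_dispatch(history, day)
        if event is not None:
            event.completed = bool(aux.random() < config.completion_prob)
            completed += event.completed

    summaries: dict[str, accel.ParticipantAccelSummary] = {}
    if config.assessment_epochs:
        for label, window in windows.items():
            epochs = pd.concat(
                [days[i].epochs for i in window], ignore_index=True
            )
            steps = {days[i].date: float(days[i].steps) for i in window}
            _, summary = accel.process_participant(epochs, steps_by_date=steps)
            summaries[label] = summary

    return ParticipantResult(
        profile=profile,
        days=days,
        scores=history,
        events=policy.log,
        completed=completed,
        accel_summaries=summaries,
        dropped_week6=bool(aux.random() < config.dropout_week6),
        dropped_week16=bool(aux.random() < config.dropout_week16),
        baseline_failed=baseline_failed,
    )


def run_cohort(
    config: CohortConfig,
    seed: int,
    catalog: list[Do] | None = None,
    score_from_gps: bool = False,
) -> CohortResult:
    """Closed-loop cohort run with study-level outputs."""
    catalog = catalog if catalog is not None else default_catalog()
    root = np.random.SeedSequence(seed)
    participants = []
    for pid, ss in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(ss)
        profile = sample_profile(pid, rng, responsiveness=config.responsiveness)
        participants.append(
            run_participant(profile, config, catalog, score_from_gps)
        )

    labels = list(config.assessment_windows())
    summaries: list[stats.TimepointSummary] = []
    effect_sizes: dict[str, stats.EffectSize] = {}
    plan = None
    table = pd.DataFrame()

    if config.assessment_epochs and participants:
        outcome_keys = [k for k, _ in stats.TABLE_OUTCOMES]
        wide = {
            k: pd.DataFrame(
                {
                    label: [
                        getattr(p.accel_summaries[label], k)
                        if _assessed(p, label)
                        else np.nan
                        for p in participants
                    ]
                    for label in labels
                }
            )
            for k in outcome_keys
        }
        filled = {k: stats.locf(v, labels) for k, v in wide.items()}
        for label in labels:
            summaries.append(
                stats.summarize_timepoint(
                    label, {k: filled[k][label] for k in outcome_keys}
                )
            )
        if "week16" in labels:
            base, last = summaries[0], summaries[-1]
            for k in ("sb_min", "sb_pct_of_wear"):
                m1, s1 = base.stats[k]
                m2, s2 = last.stats[k]
                if s1 > 0 and s2 > 0:
                    effect_sizes[k] = stats.cohen_d_two_timepoints(
                        m1, s1, m2, s2, outcome=k
                    )
            d_sb = effect_sizes.get("sb_min")
            if d_sb is not None and d_sb.cohen_d > 0:
                plan = stats.inflate_for_dropout(
                    stats.sample_size_two_group_t(d_sb.cohen_d),
                    config.dropout_week16,
                )
        table = stats.cohort_table(summaries)

    all_events = [e for p in participants for e in p.events]
    return CohortResult(
        participants=participants,
        summaries=summaries,
        effect_sizes=effect_sizes,
        plan=plan,
        adherence=adherence_pct(all_events),
        table=table,
    )


def _assessed(p: ParticipantResult, label: str) -> bool:
    if label == "week6":
        return not p.dropped_week6
    if label == "week16":
        return not p.dropped_week16
    return True


def write_simulation(config: CohortConfig, seed: int, outdir) -> Path:
    """Materialise cohort streams to disk in the reader dialects:
    per-participant epoch CSVs (assessment weeks), GPS CSVs, intake JSON and
    the truth record."""
    from dataclasses import asdict

    from .simulate import simulate_cohort, truth_record

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config, seed, with_gps=True)
    for part in cohort:
        pdir = outdir / f"participant_{part['profile'].pid:03d}"
        pdir.mkdir(exist_ok=True)
        windows = config.assessment_windows()
        for label, window in windows.items():
            frames = [part["days"][i].epochs for i in window
                      if part["days"][i].epochs is not None]
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    pdir / f"epochs_{label}.csv", index=False
                )
        gps_frames = [d.gps for d in part["days"] if d.gps is not None]
        if gps_frames:
            pd.concat(gps_frames, ignore_index=True).to_csv(
                pdir / "gps.csv", index=False
            )
        with open(pdir / "intake.json", "w", encoding="utf-8") as fh:
            json.dump([asdict(r) for r in part["intake"]], fh, indent=1)
        with open(pdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth_record(part), fh)
    return outdir


def write_report(result: CohortResult, outdir) -> Path:
    """Write the cohort report: outcome table CSV, dispatch log JSON-lines,
    adherence, effect sizes, and the sample-size plan."""
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "outcome_table.csv", index=False)
    with open(outdir / "dispatch_log.jsonl", "w", encoding="utf-8") as fh:
        for p in result.participants:
            for e in p.events:
                row = asdict(e)
                row["date"] = e.date.isoformat()
                row["pid"] = p.profile.pid
                fh.write(json.dumps(row) + "\n")
    report = {
        "n_participants": len(result.participants),
        "adherence_pct": result.adherence,
        "effect_sizes": {
            k: v.cohen_d for k, v in result.effect_sizes.items()
        },
        "dos_per_participant": [p.n_dispatched for p in result.participants],
        "sample_size_plan": asdict(result.plan) if result.plan else None,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return outdir
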