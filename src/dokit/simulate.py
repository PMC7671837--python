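"""Synthetic free-living cohort simulator.

Generates multi-week per-participant data streams — 15-second triaxial
epoch counts, device-reported daily steps, GPS fixes, intake-questionnaire
answers — whose baseline magnitudes emulate a sedentary adult cardiac-
rehabilitation population (roughly 11-12 h/day sitting, ~7,900 steps/day,
~74 min/day MVPA, ~18 h/day wear, daily mobility among a small set of
recurring places with occasional novel ones).

Three design features matter downstream:

* **Slump states.** A shared two-state Markov chain (an "off week":
  illness, workload) plus one chain per behavioural variable (physical
  activity, social opportunity, variety), each with mean slump length
  ~4.5 days. Slumps raise sitting time, suppress outings and novelty, and
  give the day series the multi-day autocorrelation that real behaviour
  shows; without it, three consecutive low-scoring days would almost never
  occur and the dispatch engine would sit idle.
* **Exact day totals.** Sedentary/light/MVPA minutes are scheduled as
  alternating runs whose lengths are drawn stochastically but partitioned
  to sum exactly to the day's target totals, so the generative truth is
  well defined and recovery can be checked tightly.
* **Responsiveness.** Each completed Do lowers the participant's target
  sitting time by ``responsiveness`` minutes (default −9.2 min per
  completed Do, sized so a typical program's completed-Do count accumulates
  to a reduction of roughly 107 min/day), realised by shortening sedentary
  run lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .catalog import INTAKE_ITEMS
from .engine import IntakeResponse, RawDailyVariables

MINUTES_PER_DAY = 1440
EPOCHS_PER_MINUTE = 4

# population-level defaults (see docs/methods.md for the derivation)
POPULATION = dict(
    wear_min_low=840.0, wear_min_high=1316.0,   # daily wear minutes (uniform)
    sb_frac_low=0.41, sb_frac_high=0.91,        # non-slump sitting as a
    #                                             fraction of wear (uniform)
    slump_gain=0.07,                            # slump raises SB by 7%
    # shared slump (illness / workload weeks: all variables dip together)
    global_slump_enter=0.13, global_slump_exit=0.22,    # ~37% occupancy, ~4.5 d
    # per-variable slumps on top of the shared one
    slump_enter=0.12, slump_exit=0.22,                  # ~35% occupancy, ~4.5 d
    day_noise_sd=0.045,                          # lognormal day-to-day noise
    sed_run_mean=12.5, sed_run_sigma=1.1,       # lognormal run lengths (min)
    mvpa_run_mean=8.0,
    mvpa_frac_mean=0.215, mvpa_frac_sd=0.05,    # MVPA share of active time
    wake_h_mean=6.2, wake_h_sd=0.6,
    steps_per_mvpa_min=88.0, steps_per_light_min=6.0,
    sed_zero_prob=0.30,                         # zero-count sedentary minutes
    sed_cpm_scale=61.0, light_cpm_scale=800.0, mvpa_cpm_scale=510.0,
    bad_coverage_prob=0.02,
    novel_place_rate=0.9,                       # new places/day when active
    responsiveness=-9.2,                        # min SB per completed Do
)

_HOME = (-35.30, 149.12)  # reference urban coordinate frame
_KM_PER_DEG_LAT = 111.2


@dataclass
class ParticipantProfile:
    """Generative parameters for one participant (the truth record)."""

    pid: int
    seed: int
    wear_min: float
    base_sb_min: float
    wake_h: float
    sed_run_mean: float
    mvpa_frac: float
    responsiveness: float
    novel_rate: float
    worker: bool
    home: tuple[float, float]
    work: tuple[float, float]
    recurring: list[tuple[float, float]]
    slump_gain: float = POPULATION["slump_gain"]
    day_noise_sd: float = POPULATION["day_noise_sd"]
    bad_coverage_prob: float = POPULATION["bad_coverage_prob"]

    @property
    def heavy_sitter(self) -> bool:
        midpoint = (POPULATION["sb_frac_low"] + POPULATION["sb_frac_high"]) / 2
        return self.base_sb_min >= midpoint * self.wear_min


def _offset(origin, km, bearing_rad):
    dlat = km * np.cos(bearing_rad) / _KM_PER_DEG_LAT
    dlon = km * np.sin(bearing_rad) / (
        _KM_PER_DEG_LAT * np.cos(np.radians(origin[0]))
    )
    return (origin[0] + dlat, origin[1] + dlon)


def sample_profile(
    pid: int, rng: np.random.Generator, responsiveness: float | None = None
) -> ParticipantProfile:
    """Draw one participant from the population."""
    p = POPULATION
    wear = float(rng.uniform(p["wear_min_low"], p["wear_min_high"]))
    base_sb = float(rng.uniform(p["sb_frac_low"], p["sb_frac_high"]) * wear)
    home = (
        _HOME[0] + rng.uniform(-0.05, 0.05),
        _HOME[1] + rng.uniform(-0.06, 0.06),
    )
    work = _offset(home, rng.uniform(3, 8), rng.uniform(0, 2 * np.pi))
    recurring = [
        _offset(home, rng.uniform(1, 6), rng.uniform(0, 2 * np.pi))
        for _ in range(6)
    ]
    return ParticipantProfile(
        pid=pid,
        seed=int(rng.integers(0, 2**31 - 1)),
        wear_min=wear,
        base_sb_min=base_sb,
        wake_h=float(np.clip(rng.normal(p["wake_h_mean"], p["wake_h_sd"]), 4.5, 9.0)),
        sed_run_mean=float(np.clip(rng.normal(p["sed_run_mean"], 1.5), 8.0, 20.0)),
        mvpa_frac=float(np.clip(rng.normal(p["mvpa_frac_mean"], p["mvpa_frac_sd"]), 0.03, 0.45)),
        responsiveness=(
            p["responsiveness"] if responsiveness is None else responsiveness
        ),
        novel_rate=p["novel_place_rate"],
        worker=bool(rng.random() < 0.67),
        home=home,
        work=work,
        recurring=recurring,
    )


@dataclass
class DayRecord:
    """One simulated day: generative truth, engine inputs, optional streams."""

    date: Date
    wear_min: int
    sb_min: int
    light_min: int
    mvpa_min: int
    steps: int
    coverage: float
    slumps: dict[str, bool]
    raw: RawDailyVariables
    epochs: pd.DataFrame | None = None
    gps: pd.DataFrame | None = None


def _int_partition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Split `total` into `parts` positive integers, multinomially."""
    if parts <= 0:
        return np.zeros(0, dtype=int)
    if total < parts:
        out = np.zeros(parts, dtype=int)
        out[:total] = 1
        return out
    return rng.multinomial(total - parts, np.full(parts, 1.0 / parts)) + 1


class ParticipantSimulator:
    """Day-by-day generator for one participant (deterministic per seed)."""

    VARS = ("pa", "social", "variety")

    def __init__(self, profile: ParticipantProfile):
        self.profile = profile
        self.rng = np.random.default_rng(profile.seed)
        p = POPULATION
        pi_g = p["global_slump_enter"] / (p["global_slump_enter"] + p["global_slump_exit"])
        pi_v = p["slump_enter"] / (p["slump_enter"] + p["slump_exit"])
        self.global_slump = bool(self.rng.random() < pi_g)
        self._var_slump = {v: bool(self.rng.random() < pi_v) for v in self.VARS}

    @property
    def slump(self) -> dict[str, bool]:
        """Effective slump per variable: shared state OR its own chain."""
        g = self.global_slump
        return {v: g or s for v, s in self._var_slump.items()}

    # -- latent dynamics ---------------------------------------------------
    def _advance_slumps(self) -> None:
        p = POPULATION
        u = self.rng.random()
        if self.global_slump:
            self.global_slump = u >= p["global_slump_exit"]
        else:
            self.global_slump = u < p["global_slump_enter"]
        for v in self.VARS:
            u = self.rng.random()
            if self._var_slump[v]:
                self._var_slump[v] = u >= p["slump_exit"]
            else:
                self._var_slump[v] = u < p["slump_enter"]

    # -- one day -----------------------------------------------------------
    def simulate_day(
        self,
        day: Date,
        completed_dos: int,
        with_epochs: bool = False,
        with_gps: bool = False,
    ) -> DayRecord:
        pr, rng = self.profile, self.rng
        self._advance_slumps()
        s_pa, s_soc, s_var = (self.slump[v] for v in self.VARS)

        wear = int(np.clip(round(rng.normal(pr.wear_min, 25)), 690, 1380))
        target = pr.base_sb_min * (1.0 + pr.slump_gain * s_pa)
        target += pr.responsiveness * completed_dos
        target *= float(np.exp(rng.normal(0.0, pr.day_noise_sd)))
        sb = int(np.clip(round(target), 240, wear - 60))
        active = wear - sb
        mvpa = int(np.clip(round(active * np.clip(rng.normal(pr.mvpa_frac, 0.03), 0.0, 0.5)), 0, active))
        light = active - mvpa
        steps = int(
            max(
                0.0,
                round(
                    mvpa * rng.normal(POPULATION["steps_per_mvpa_min"], 8)
                    + light * rng.normal(POPULATION["steps_per_light_min"], 2)
                    + rng.normal(0, 200)
                ),
            )
        )

        if rng.random() < pr.bad_coverage_prob:
            coverage = float(rng.uniform(0.20, 0.55))
        else:
            coverage = float(rng.uniform(0.82, 1.0))

        mob = self._mobility_truth(s_soc, s_var, steps)
        raw = RawDailyVariables(
            date=day,
            coverage=coverage,
            pa={"steps": float(steps), "active_min": float(active)},
            social={
                "n_new_places": mob["n_new_places"],
                "dwell_in_new_places_min": mob["dwell_in_new_places_min"],
            },
            variety={
                "n_uncommon_places": mob["n_uncommon_places"],
                "distance_km": mob["distance_km"],
                "route_dissimilarity": mob["route_dissimilarity"],
                "timing_shift": mob["timing_shift"],
            },
        )
        rec = DayRecord(
            date=day,
            wear_min=wear,
            sb_min=sb,
            light_min=light,
            mvpa_min=mvpa,
            steps=steps,
            coverage=coverage,
            slumps=dict(self.slump),
            raw=raw,
        )
        # streams draw from day-keyed child generators so the daily truth is
        # byte-identical whether or not streams are materialised
        if with_epochs:
            rec.epochs = self._make_epochs(
                day, wear, sb, light, mvpa,
                np.random.default_rng([self.profile.seed, day.toordinal(), 1]),
            )
        if with_gps:
            rec.gps = self._make_gps(
                day, mob,
                np.random.default_rng([self.profile.seed, day.toordinal(), 2]),
            )
        return rec

    def _mobility_truth(self, s_soc: bool, s_var: bool, steps: int) -> dict:
        rng, pr = self.rng, self.profile
        n_new = int(rng.poisson(0.10 if s_soc else pr.novel_rate))
        dwell_new = float(rng.exponential(45.0) * n_new) if n_new else 0.0
        n_unc = int(rng.poisson(0.08 if s_var else 1.0))
        dist = float(rng.lognormal(np.log(4.0 if s_var else 18.0), 0.45))
        dissim = float(rng.uniform(0.0, 0.15) if s_var else rng.uniform(0.25, 0.70))
        tshift = float(rng.uniform(0.0, 0.08) if s_var else rng.uniform(0.05, 0.40))
        return dict(
            n_new_places=float(n_new),
            dwell_in_new_places_min=dwell_new,
            n_uncommon_places=float(n_unc),
            distance_km=dist,
            route_dissimilarity=dissim,
            timing_shift=tshift,
        )

    # -- epoch stream ------------------------------------------------------
    def _day_schedule(
        self, sb: int, light: int, mvpa: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Per-wear-minute intensity codes (1 sed, 2 light, 3 mvpa) as
        alternating sedentary/active runs summing exactly to the targets."""
        pr = self.profile
        p = POPULATION
        mu = np.log(pr.sed_run_mean) - p["sed_run_sigma"] ** 2 / 2.0
        # enough sedentary runs to cover sb minutes
        runs: list[int] = []
        total = 0
        while total < sb:
            draw = rng.lognormal(mu, p["sed_run_sigma"], size=32)
            for x in np.maximum(1, np.rint(draw)).astype(int):
                if total >= sb:
                    break
                run = min(int(x), sb - total)
                runs.append(run)
                total += run
        n_s = len(runs)
        k_m = min(n_s, max(1, round(mvpa / p["mvpa_run_mean"]))) if mvpa > 0 else 0
        mvpa_runs = _int_partition(mvpa, k_m, rng)
        light_runs = _int_partition(light, max(n_s - k_m, 1 if light else 0), rng)
        active = [(2, int(x)) for x in light_runs if x > 0] + [
            (3, int(x)) for x in mvpa_runs if x > 0
        ]
        rng.shuffle(active)
        seq: list[tuple[int, int]] = []
        for i, srun in enumerate(runs):
            seq.append((1, srun))
            if i < len(active):
                seq.append(active[i])
        seq.extend(active[len(runs):])
        codes = np.concatenate(
            [np.full(n, code, dtype=np.int8) for code, n in seq]
        )
        return codes

    def _make_epochs(
        self,
        day: Date,
        wear: int,
        sb: int,
        light: int,
        mvpa: int,
        rng: np.random.Generator,
    ) -> pd.DataFrame:
        """Materialise a full midnight-to-midnight 15-s epoch stream."""
        pr = self.profile
        p = POPULATION
        wake = int(round(pr.wake_h * 60 + rng.normal(0, 15)))
        wake = max(0, min(wake, MINUTES_PER_DAY - wear))
        codes = np.zeros(MINUTES_PER_DAY, dtype=np.int8)
        codes[wake : wake + wear] = self._day_schedule(sb, light, mvpa, rng)

        cpm = np.zeros(MINUTES_PER_DAY)
        sed = codes == 1
        nz = sed & (rng.random(MINUTES_PER_DAY) >= p["sed_zero_prob"])
        cpm[nz] = 1 + np.minimum(
            np.floor(rng.exponential(p["sed_cpm_scale"], nz.sum())), 148
        )
        li = codes == 2
        cpm[li] = 150 + np.minimum(
            np.floor(rng.exponential(p["light_cpm_scale"], li.sum())), 2539
        )
        mv = codes == 3
        cpm[mv] = 2690 + np.minimum(
            np.floor(rng.exponential(p["mvpa_cpm_scale"], mv.sum())), 9000
        )

        w = rng.standard_exponential((MINUTES_PER_DAY, EPOCHS_PER_MINUTE))
        w /= w.sum(axis=1, keepdims=True)
        vm = (cpm[:, None] * w).ravel()
        # triaxial decomposition with (near-)unit-norm direction cosines
        ax = np.rint(0.588 * vm).astype(np.int64)
        ay = np.rint(0.784 * vm).astype(np.int64)
        az = np.rint(0.196 * vm).astype(np.int64)
        ts = pd.date_range(
            start=pd.Timestamp(day),
            periods=MINUTES_PER_DAY * EPOCHS_PER_MINUTE,
            freq="15s",
        )
        return pd.DataFrame({"timestamp": ts, "ax": ax, "ay": ay, "az": az})

    # -- GPS stream --------------------------------------------------------
    def _make_gps(
        self, day: Date, mob: dict, rng: np.random.Generator
    ) -> pd.DataFrame:
        """Fixes along the day's itinerary: 1/5 min during stays, 1/min in
        transit at ~30 km/h, Gaussian jitter sigma = 15 m."""
        pr = self.profile
        wake = int(pr.wake_h * 60)
        stops: list[tuple[tuple[float, float], int]] = []  # (coord, dwell)
        if pr.worker and day.weekday() < 5:
            stops.append((pr.work, 8 * 60))
        k = int(rng.poisson(1.0))
        for idx in rng.choice(len(pr.recurring), size=min(k, 3), replace=False):
            stops.append((pr.recurring[idx], int(rng.uniform(20, 45))))
        for _ in range(int(mob["n_new_places"])):
            novel = _offset(pr.home, rng.uniform(1, 10), rng.uniform(0, 2 * np.pi))
            stops.append((novel, int(rng.uniform(20, 60))))

        lat, lon, tmin = [], [], []

        def stay(coord, t0, t1):
            for t in range(t0, t1, 5):
                lat.append(coord[0])
                lon.append(coord[1])
                tmin.append(t)

        def transit(a, b, t0):
            km = (
                np.hypot(
                    (b[0] - a[0]) * _KM_PER_DEG_LAT,
                    (b[1] - a[1]) * _KM_PER_DEG_LAT * np.cos(np.radians(a[0])),
                )
            )
            dur = max(2, int(round(km / 30.0 * 60)))
            for i in range(dur):
                f = i / dur
                lat.append(a[0] + f * (b[0] - a[0]))
                lon.append(a[1] + f * (b[1] - a[1]))
                tmin.append(t0 + i)
            return t0 + dur

        t = 0
        stay(pr.home, 0, wake)
        here = pr.home
        t = wake
        for coord, dwell in stops:
            t = transit(here, coord, t)
            if t + dwell >= MINUTES_PER_DAY - 60:
                break
            stay(coord, t, t + dwell)
            t += dwell
            here = coord
        t = transit(here, pr.home, t)
        stay(pr.home, min(t, MINUTES_PER_DAY - 1), MINUTES_PER_DAY)

        lat = np.asarray(lat) + rng.normal(0, 15.0 / 111_200, len(lat))
        lon = np.asarray(lon) + rng.normal(
            0, 15.0 / (111_200 * np.cos(np.radians(pr.home[0]))), len(lon)
        )
        ts = pd.Timestamp(day) + pd.to_timedelta(np.asarray(tmin), unit="m")
        return pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})


def generate_intake(
    profile: ParticipantProfile, rng: np.random.Generator
) -> list[IntakeResponse]:
    """Ordinal 1-5 intake answers correlated with the profile.

    Heavy sitters answer "often"/"always" (>=4) to the sedentary-habit items
    with probability 0.8 (0.25 otherwise); mobility-habit items use softer
    probabilities tied to the novelty rate.
    """
    sed_items = {
        "screen_evening", "sit_work", "meals_seated_screen",
        "calls_seated", "lift_over_stairs",
    }
    out = []
    for item_id, _text in INTAKE_ITEMS:
        if item_id in sed_items:
            p_high = 0.8 if profile.heavy_sitter else 0.45
        elif item_id == "car_short_trips":
            p_high = 0.5
        else:  # same_route, evenings_home — routine-boundness
            p_high = 0.55
        if rng.random() < p_high:
            answer = int(rng.choice([4, 5]))
        else:
            answer = int(rng.choice([1, 2, 3]))
        out.append(IntakeResponse(item_id=item_id, answer=answer))
    return out


@dataclass
class CohortConfig:
    """Study-shaped cohort: a 7-day profiling/baseline week, a 6-week
    dispatch window, assessments at 0/6/16 weeks, dropout at follow-up."""

    n_participants: int = 20
    weeks: int = 16
    start_date: Date = Date(2019, 1, 7)  # a Monday: program weeks = ISO weeks
    baseline_days: int = 7
    dispatch_weeks: int = 6
    dropout_week6: float = 0.05
    dropout_week16: float = 0.40
    completion_prob: float = 0.737       # Do-completion (adherence) rate
    responsiveness: float | None = None  # None -> population default
    assessment_epochs: bool = True       # materialise epoch streams at 0/6/16

    @property
    def n_days(self) -> int:
        return self.weeks * 7

    def assessment_windows(self) -> dict[str, range]:
        """Day-index ranges of the 7-day accelerometer wear periods."""
        w = {"baseline": range(0, 7)}
        if self.weeks >= 7:
            w["week6"] = range(42, 49)
        if self.weeks >= 16:
            w["week16"] = range(105, 112)
        return w

    @property
    def dispatch_days(self) -> range:
        return range(self.baseline_days, self.baseline_days + 7 * self.dispatch_weeks)


def simulate_cohort(
    config: CohortConfig, seed: int, with_gps: bool = False
) -> list[dict]:
    """Open-loop cohort streams plus the truth record.

    Each participant's generative parameters are stored for recovery tests;
    dropout flags are drawn for the follow-up assessments. Do feedback
    (closed-loop responsiveness) lives in :mod:`dokit.pipeline`, which
    couples this generator to the dispatch engine.
    """
    root = np.random.SeedSequence(seed)
    out = []
    for pid, ss in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(ss)
        profile = sample_profile(pid, rng, responsiveness=config.responsiveness)
        sim = ParticipantSimulator(profile)
        windows = config.assessment_windows()
        epoch_days = set().union(*windows.values()) if config.assessment_epochs else set()
        days = [
            sim.simulate_day(
                config.start_date + timedelta(days=i),
                completed_dos=0,
                with_epochs=i in epoch_days,
                with_gps=with_gps,
            )
            for i in range(config.n_days)
        ]
        out.append(
            dict(
                profile=profile,
                intake=generate_intake(profile, rng),
                days=days,
                dropped_week6=bool(rng.random() < config.dropout_week6),
                dropped_week16=bool(rng.random() < config.dropout_week16),
            )
        )
    return out


def truth_record(participant: dict) -> dict:
    """JSON-serialisable generative truth for one simulated participant."""
    profile: ParticipantProfile = participant["profile"]
    return {
        "profile": {
            k: v
            for k, v in asdict(profile).items()
            if not isinstance(v, (list, tuple))
        },
        "dropped_week6": participant["dropped_week6"],
        "dropped_week16": participant["dropped_week16"],
        "days": [
            {
                "date": d.date.isoformat(),
                "wear_min": d.wear_min,
                "sb_min": d.sb_min,
                "light_min": d.light_min,
                "mvpa_min": d.mvpa_min,
                "steps": d.steps,
                "coverage": d.coverage,
                "slumps": d.slumps,
            }
            for d in participant["days"]
        ],
    }
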