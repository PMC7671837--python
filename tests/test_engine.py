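"""Behavioural scoring and dispatch: baseline profiling, 0-10 rescaling,
face feedback, trigger rules, weekly caps, core selection, adherence."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dokit import engine
from dokit.catalog import DATA_DRIVEN, default_catalog
from dokit.engine import (
    BaselineProfile,
    DailyScores,
    DispatchEvent,
    DispatchPolicy,
    IntakeResponse,
    RawDailyVariables,
    adherence,
    compute_baseline,
    daily_scores,
    fourteen_day_overview,
    rescale,
    select_core_dos,
)

MON = date(2019, 1, 14)


def raw_day(d, coverage=0.9, steps=6000.0, active=300.0, new=1.0, dwell=30.0,
            unc=1.0, dist=15.0, dissim=0.4, shift=0.2):
    return RawDailyVariables(
        date=d,
        coverage=coverage,
        pa={"steps": steps, "active_min": active},
        social={"n_new_places": new, "dwell_in_new_places_min": dwell},
        variety={"n_uncommon_places": unc, "distance_km": dist,
                 "route_dissimilarity": dissim, "timing_shift": shift},
    )


def week_of_raws(**kw):
    return [raw_day(MON + timedelta(days=i), **kw) for i in range(7)]


class TestBaseline:
    def test_bounds_span_the_week(self):
        week = [raw_day(MON + timedelta(days=i), steps=4000 + 1000 * (i % 6))
                for i in range(7)]
        b = compute_baseline(week)
        assert b.bounds["pa"]["steps"] == (4000, 9000)

    def test_constant_variable_degenerates(self):
        b = compute_baseline(week_of_raws(steps=5000))
        lo, hi = b.bounds["pa"]["steps"]
        assert lo == hi == 5000

    def test_low_coverage_day_excluded(self):
        week = week_of_raws(steps=6000)
        week[3] = raw_day(week[3].date, coverage=0.30, steps=100.0)
        b = compute_baseline(week)
        assert b.bounds["pa"]["steps"] == (6000, 6000)
        assert b.n_days_used == 6

    def test_insufficient_baseline(self):
        week = [raw_day(MON + timedelta(days=i), coverage=0.2) for i in range(7)]
        week[0] = raw_day(MON, coverage=0.9)
        week[1] = raw_day(MON + timedelta(days=1), coverage=0.9)
        with pytest.raises(engine.InsufficientBaselineError, match="insufficient"):
            compute_baseline(week)

    def test_requires_seven_days(self):
        with pytest.raises(ValueError):
            compute_baseline(week_of_raws()[:5])


class TestRescale:
    @pytest.mark.parametrize(
        "value,lo,hi,expected",
        [
            (6500, 4000, 9000, 5.0),
            (3000, 4000, 9000, 0.0),   # at or below the minimum
            (4000, 4000, 9000, 0.0),
            (9500, 4000, 9000, 10.0),  # at or above the maximum
            (9000, 4000, 9000, 10.0),
            (123, 50, 50, 5.0),        # degenerate baseline -> neutral
        ],
    )
    def test_examples(self, value, lo, hi, expected):
        assert rescale(value, lo, hi) == pytest.approx(expected)

    def test_min_above_max_errors(self):
        with pytest.raises(ValueError):
            rescale(5, 10, 1)

    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(-1e6, 1e6, allow_nan=False),
    )
    @settings(deadline=None)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = 100.0, 900.0
        x, y = min(a, b), max(a, b)
        rx, ry = rescale(x, lo, hi), rescale(y, lo, hi)
        assert 0.0 <= rx <= ry <= 10.0


class TestDailyScores:
    def _baseline(self):
        week = [raw_day(MON + timedelta(days=i), steps=4000 + i * 500,
                        active=200 + i * 20, new=float(i % 3), dwell=10.0 * (i % 3),
                        unc=float(i % 2), dist=5.0 + i, dissim=0.1 * i,
                        shift=0.05 * i)
                for i in range(7)]
        return compute_baseline(week)

    def test_all_at_max_scores_ten(self):
        b = self._baseline()
        top = raw_day(MON + timedelta(days=9), steps=1e6, active=1e6, new=99,
                      dwell=1e5, unc=99, dist=1e4, dissim=1.0, shift=1.0)
        s = daily_scores(top, b)
        assert (s.pa, s.social, s.variety) == (10.0, 10.0, 10.0)
        assert set(s.faces.values()) == {"smiley"}

    def test_all_at_min_scores_zero(self):
        b = self._baseline()
        bottom = raw_day(MON + timedelta(days=9), steps=0, active=0, new=0,
                         dwell=0, unc=0, dist=0, dissim=0, shift=0)
        s = daily_scores(bottom, b)
        assert (s.pa, s.social, s.variety) == (0.0, 0.0, 0.0)
        assert set(s.faces.values()) == {"sad"}

    def test_equal_weight_mean(self):
        b = BaselineProfile(
            bounds={
                "pa": {"steps": (0, 10), "active_min": (0, 10)},
                "social": {"n_new_places": (0, 1), "dwell_in_new_places_min": (0, 1)},
                "variety": {"n_uncommon_places": (0, 1), "distance_km": (0, 1),
                            "route_dissimilarity": (0, 1), "timing_shift": (0, 1)},
            },
            n_days_used=7,
        )
        raw = raw_day(MON, steps=4.0, active=6.0, new=1, dwell=1, unc=1,
                      dist=1, dissim=1, shift=1)
        s = daily_scores(raw, b)
        assert s.pa == pytest.approx(5.0)  # mean of rescaled 4 and 6
        assert s.faces["pa"] == "neutral"

    @given(st.floats(0, 1e9, allow_nan=False), st.floats(0, 1e9, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_scores_always_in_range(self, steps, active):
        b = self._baseline()
        raw = raw_day(MON, steps=steps, active=active)
        s = daily_scores(raw, b)
        for v in ("pa", "social", "variety"):
            assert 0.0 <= s.score(v) <= 10.0


def scores_seq(values, start=MON, coverage=0.9, var="pa"):
    out = []
    for i, v in enumerate(values):
        kw = {"pa": 8.0, "social": 8.0, "variety": 8.0}
        kw[var] = v
        cov = coverage[i] if isinstance(coverage, (list, tuple)) else coverage
        out.append(DailyScores(date=start + timedelta(days=i), coverage=cov,
                               faces={}, **kw))
    return out


class TestDispatch:
    def test_three_low_days_trigger_pa_do(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        hist = scores_seq([2.0, 2.0, 2.0], coverage=[0.8, 0.9, 0.7])
        ev = policy.check_dispatch(hist, hist[-1].date)
        assert ev is not None
        assert ev.trigger == "low_score:pa"
        do = next(d for d in catalog if d.do_id == ev.do_id)
        assert do.kind == DATA_DRIVEN and do.target == "pa"

    def test_coverage_gate_blocks(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        hist = scores_seq([2.0, 2.0, 2.0], coverage=[0.8, 0.55, 0.9])
        assert policy.check_dispatch(hist, hist[-1].date) is None

    def test_weekly_cap_blocks(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        for k in range(3):
            policy.record(DispatchEvent(do_id=50 + k, date=MON, trigger="core_schedule"))
        hist = scores_seq([2.0, 2.0, 2.0], start=MON + timedelta(days=2))
        assert policy.check_dispatch(hist, hist[-1].date) is None

    def test_two_low_days_insufficient(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        hist = scores_seq([8.0, 2.0, 2.0])
        assert policy.check_dispatch(hist, hist[-1].date) is None

    def test_tie_broken_by_lowest_mean_then_fixed_order(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        hist = scores_seq([2.0, 2.0, 2.0], var="social")
        for s in hist:
            s.variety = 1.0  # lower 3-day mean than social
        ev = policy.check_dispatch(hist, hist[-1].date)
        assert ev.trigger == "low_score:variety"

        policy2 = DispatchPolicy(catalog, seed=5)
        hist2 = scores_seq([2.0, 2.0, 2.0], var="social")
        for s in hist2:
            s.pa = 2.0  # equal means: fixed order prefers pa
        ev2 = policy2.check_dispatch(hist2, hist2[-1].date)
        assert ev2.trigger == "low_score:pa"

    def test_dispatch_resets_streak(self, catalog):
        policy = DispatchPolicy(catalog, seed=5)
        hist = scores_seq([2.0] * 6)
        assert policy.check_dispatch(hist[:3], hist[2].date) is not None
        # days 4-5 are only 2 fresh lows after the dispatch
        assert policy.check_dispatch(hist[:4], hist[3].date) is None
        assert policy.check_dispatch(hist[:5], hist[4].date) is None
        assert policy.check_dispatch(hist[:6], hist[5].date) is not None

    def test_no_repeat_do_ids_and_determinism(self, catalog):
        def run():
            policy = DispatchPolicy(catalog, seed=99)
            sent = []
            hist = []
            for i in range(60):
                day = MON + timedelta(days=i)
                hist.append(DailyScores(date=day, pa=1.0, social=8.0,
                                        variety=8.0, coverage=0.9, faces={}))
                ev = policy.check_dispatch(hist, day)
                if ev:
                    sent.append(ev.do_id)
            return sent

        a, b = run(), run()
        assert a == b
        assert len(a) == len(set(a))

    def test_exhausted_catalog_warns_and_skips(self, catalog):
        small = [d for d in catalog if d.kind == DATA_DRIVEN and d.target == "pa"][:1]
        policy = DispatchPolicy(small, seed=5)
        hist = scores_seq([1.0] * 3)
        assert policy.check_dispatch(hist, hist[-1].date) is not None
        hist2 = scores_seq([1.0] * 3, start=MON + timedelta(days=10))
        assert policy.check_dispatch(hist2, hist2[-1].date) is None

    def test_functional_wrapper_replays_log(self, catalog):
        hist = scores_seq([2.0, 2.0, 2.0])
        log = [DispatchEvent(do_id=1, date=MON, trigger="core_schedule")] * 3
        assert engine.check_dispatch(hist, log, catalog, hist[-1].date) is None
        assert engine.check_dispatch(hist, [], catalog, hist[-1].date) is not None


class TestCoreSelection:
    def test_screen_time_habit_activates_screen_dos(self, catalog):
        intake = [IntakeResponse("screen_evening", 5)]
        dos = select_core_dos(intake, catalog)
        assert any("screen" in d.text.lower() or "episode" in d.text.lower()
                   for d in dos)
        assert all(d.kind == "core" for d in dos)

    def test_all_never_activates_nothing(self, catalog):
        intake = [IntakeResponse(item, 1) for item in
                  {r["item"] for d in catalog for r in d.activation_rules}]
        assert select_core_dos(intake, catalog) == []

    def test_priority_order(self, catalog):
        intake = [IntakeResponse("screen_evening", 5), IntakeResponse("sit_work", 4)]
        dos = select_core_dos(intake, catalog)
        assert [d.priority for d in dos] == sorted(d.priority for d in dos)
        assert len(dos) == 4  # two Dos per matched habit item

    def test_empty_intake_empty_schedule(self, catalog):
        assert select_core_dos([], catalog) == []


class TestAdherence:
    def test_printed_ratio(self):
        log = [DispatchEvent(i, MON, "core_schedule", completed=i < 252)
               for i in range(342)]
        assert adherence(log) == 73.7

    def test_none_completed(self):
        log = [DispatchEvent(i, MON, "core_schedule") for i in range(10)]
        assert adherence(log) == 0.0

    def test_seven_of_eight(self):
        log = [DispatchEvent(i, MON, "core_schedule", completed=i < 7)
               for i in range(8)]
        assert adherence(log) == 87.5

    def test_undefined_when_empty(self):
        assert adherence([]) is None


class TestOverview:
    def test_all_smileys(self):
        scores = scores_seq([10.0] * 14)
        grid = fourteen_day_overview(scores)
        assert sum(row.count("smiley") for row in grid.values()) == 42

    def test_alternating_faces(self):
        scores = scores_seq([0.0, 10.0] * 7)
        grid = fourteen_day_overview(scores)
        assert grid["pa"] == ["sad", "smiley"] * 7

    def test_low_coverage_day_blank(self):
        scores = scores_seq([10.0] * 3, coverage=[0.9, 0.5, 0.9])
        grid = fourteen_day_overview(scores)
        assert grid["pa"] == ["smiley", "", "smiley"]

    def test_window_limited_to_14(self):
        scores = scores_seq([10.0] * 20)
        grid = fourteen_day_overview(scores)
        assert all(len(row) == 14 for row in grid.values())


def test_default_catalog_shape(catalog):
    assert len(catalog) == 89
    assert sum(d.sb_pa_targeted for d in catalog) == 30
    assert len({d.do_id for d in catalog}) == 89
    kinds = {d.kind for d in catalog}
    assert kinds == {"core", "data_driven"}


def test_catalog_json_roundtrip(tmp_path, catalog):
    from dokit.catalog import load_catalog, write_catalog

    path = tmp_path / "catalog.json"
    write_catalog(catalog, path)
    back = load_catalog(path)
    assert back == catalog


class TestEngineConfig:
    def test_defaults_align_low_with_sad_band(self):
        cfg = engine.EngineConfig()
        assert cfg.low_threshold == pytest.approx(cfg.face_bands[0])
        assert cfg.cap_per_week == 3

    def test_yaml_roundtrip_builds_policy(self, tmp_path, catalog):
        path = tmp_path / "engine.yaml"
        path.write_text("low_threshold: 2.5\ncap_per_week: 2\n")
        cfg = engine.EngineConfig.from_yaml(path)
        assert cfg.low_threshold == 2.5
        policy = cfg.policy(catalog, seed=1)
        assert policy.cap_per_week == 2
        hist = scores_seq([3.0, 3.0, 3.0])  # low under default, not under 2.5
        assert policy.check_dispatch(hist, hist[-1].date) is None

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            engine.EngineConfig(coverage_gate=1.5)
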