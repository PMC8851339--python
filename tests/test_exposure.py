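import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import handrisk as hr
from handrisk.exposure import SECONDS_PER_MINUTE

import bruteforce

T0 = pd.Timestamp("2017-10-10T08:00:00")


def ts(seconds):
    return T0 + pd.Timedelta(seconds=seconds)


PARAMS = hr.MetricParams()  # t_c=30 s, t_p=60 s, miss_increment=1


def room(zone_id="A", alpha=1.0):
    return hr.ZoneConfig(zone_id, "patient_room", alpha)


class TestClassifyCrossing:
    @pytest.mark.parametrize(
        "crossing,washes,expect_ok,expect_wash",
        [
            (100, [80], True, 80),     # wash inside the t_c window before
            (100, [50], False, None),  # too long before
            (100, [170], False, None), # too long after
            (100, [160], True, 160),   # exactly t_p after
            (100, [70], True, 70),     # exactly t_c before
            (110, [95], True, 95),     # exit wash covering the next entry
                                       # (combined moments 4+1, one wash)
            (100, [10, 90, 150], True, 90),  # earliest qualifying wash
        ],
    )
    def test_window(self, crossing, washes, expect_ok, expect_wash):
        ok, w = hr.classify_crossing(ts(crossing), [ts(x) for x in washes], PARAMS)
        assert ok is expect_ok
        assert w == (ts(expect_wash) if expect_wash is not None else None)


class TestHistoryUpdates:
    def test_compliant_crossing_resets_state(self):
        state = hr.StaffState("s", history=5.0, visited_rooms={"A"})
        hr.update_history_crossing(state, room("B"), compliant=True, params=PARAMS)
        assert state.history == 0.0 and state.visited_rooms == set()

    def test_missed_crossing_is_additive(self):
        state = hr.StaffState("s", history=5.0, visited_rooms={"A"})
        hr.update_history_crossing(state, room("B"), compliant=False, params=PARAMS)
        assert state.history == 6.0 and state.visited_rooms == {"A", "B"}

    def test_missed_crossing_scales_with_alpha(self):
        state = hr.StaffState("s")
        hr.update_history_crossing(state, room("B", alpha=2.5), False, PARAMS)
        assert state.history == 2.5

    def test_dwell_without_wash_adds_minutes(self):
        state = hr.StaffState("s")
        v = hr.Visit("s", "A", ts(0), ts(600))
        hr.update_history_dwell(state, v, room(), PARAMS)
        assert state.history == pytest.approx(10.0)

    def test_dwell_with_wash_resets_then_accrues(self):
        state = hr.StaffState("s", history=50.0, visited_rooms={"A", "B"})
        v = hr.Visit("s", "A", ts(0), ts(600), wash_times=[ts(480)])
        hr.update_history_dwell(state, v, room(), PARAMS)
        assert state.history == pytest.approx(2.0)
        assert state.visited_rooms == set()

    def test_zero_alpha_dwell_leaves_history(self):
        state = hr.StaffState("s", history=3.0)
        v = hr.Visit("s", "A", ts(0), ts(600))
        hr.update_history_dwell(state, v, room(alpha=0.0), PARAMS)
        assert state.history == 3.0


class TestEntranceRisk:
    def test_product_of_history_and_unique_rooms(self):
        state = hr.StaffState("s", history=13.21, visited_rooms={"A", "B", "C"})
        assert hr.entrance_risk(state) == pytest.approx(39.63)
        state = hr.StaffState("s", history=90.6, visited_rooms=set("ABCDE"))
        assert hr.entrance_risk(state) == pytest.approx(453.0)

    def test_zero_after_wash(self):
        assert hr.entrance_risk(hr.StaffState("s")) == 0.0


class TestECR:
    def test_reference_ratios(self):
        def recs(n_compliant, n):
            mk = lambda ok: hr.EntranceRecord(
                "A", "s", T0.date(), ts(0), ts(60), None, ok,
                0.0, 0, 0, 0.0, 0.0, 0.0,
            )
            return [mk(True)] * n_compliant + [mk(False)] * (n - n_compliant)

        assert hr.entrance_compliance_rate(recs(4, 7)) == pytest.approx(400 / 7)
        assert hr.entrance_compliance_rate(recs(20, 25)) == pytest.approx(80.0)
        assert hr.entrance_compliance_rate(recs(0, 1)) == 0.0
        assert math.isnan(hr.entrance_compliance_rate([]))


def build_and_replay(events, zones, params=PARAMS):
    visits = hr.sessionize(events, zones)
    return hr.compute_metrics(visits, zones, params)


def chain_log(staff="s1", alpha=1.0):
    """Wash, 20 min out, 2 min unwashed in A, 3 min out, 10 min unwashed in B.

    Hand-computed expectations (α=1):
      entrance A: missed=1, l={A}, H = 1 + 20 -> R=21, PER_A = 2*21 = 42
      entrance B: missed=3, l={A,B}, H = 3 + 25 -> R=56, PER_B = 10*56 = 560
    """
    zones = hr.ZoneTable(
        [room("A", alpha), room("B", alpha)], hallway_risk_factor=alpha
    )
    m = 60
    events = [
        hr.HygieneEvent(ts(0), staff, "handwash", ""),
        hr.HygieneEvent(ts(20 * m), staff, "zone_entry", "A"),
        hr.HygieneEvent(ts(22 * m), staff, "zone_exit", "A"),
        hr.HygieneEvent(ts(25 * m), staff, "zone_entry", "B"),
        hr.HygieneEvent(ts(35 * m), staff, "zone_exit", "B"),
    ]
    return events, zones


class TestComputeMetrics:
    def test_single_compliant_visit(self):
        zones = hr.ZoneTable([room("A")])
        events = [
            hr.HygieneEvent(ts(0), "s1", "handwash", ""),
            hr.HygieneEvent(ts(10), "s1", "zone_entry", "A"),
            hr.HygieneEvent(ts(300), "s1", "zone_exit", "A"),
            hr.HygieneEvent(ts(301), "s1", "handwash", ""),
        ]
        res = build_and_replay(events, zones)
        assert len(res.daily) == 1
        m = res.daily[0]
        assert m.ecr == 100.0 and m.per == 0.0 and m.n_entrances == 1

    def test_hand_computed_chain(self):
        events, zones = chain_log()
        res = build_and_replay(events, zones)
        by_room = {m.room_id: m for m in res.daily}
        assert by_room["A"].per == pytest.approx(42.0)
        assert by_room["B"].per == pytest.approx(560.0)
        rec_b = by_room["B"].entrances[0]
        assert rec_b.n_missed_before == 3
        assert rec_b.n_unique_rooms == 2
        assert rec_b.history_at_entry == pytest.approx(28.0)

    def test_late_wash_inside_bounds_exposure(self):
        # unwashed entrance; wash 5 min into an 8-min stay: the patient is
        # exposed for 5 minutes, not 8
        zones = hr.ZoneTable([room("A")])
        m = 60
        events = [
            hr.HygieneEvent(ts(0), "s1", "handwash", ""),
            hr.HygieneEvent(ts(10 * m), "s1", "zone_entry", "A"),
            hr.HygieneEvent(ts(15 * m), "s1", "handwash", "A"),
            hr.HygieneEvent(ts(18 * m), "s1", "zone_exit", "A"),
            hr.HygieneEvent(ts(18 * m + 10), "s1", "handwash", ""),
        ]
        res = build_and_replay(events, zones)
        rec = res.daily[0].entrances[0]
        assert not rec.compliant
        assert rec.unwashed_in_room == pytest.approx(5.0)
        # H at entry = 1 miss + 10 min outside
        assert rec.entrance_risk == pytest.approx(11.0)
        assert res.daily[0].per == pytest.approx(55.0)

    def test_compliant_entry_wash_contributes_zero_exposure(self):
        # wash 30 s after entry (inside t_p): entrance compliant, zero PER
        zones = hr.ZoneTable([room("A")])
        events = [
            hr.HygieneEvent(ts(0), "s1", "handwash", ""),
            hr.HygieneEvent(ts(1200), "s1", "zone_entry", "A"),
            hr.HygieneEvent(ts(1230), "s1", "handwash", "A"),
            hr.HygieneEvent(ts(1800), "s1", "zone_exit", "A"),
            hr.HygieneEvent(ts(1801), "s1", "handwash", ""),
        ]
        res = build_and_replay(events, zones)
        rec = res.daily[0].entrances[0]
        assert rec.compliant and rec.unwashed_in_room == 0.0
        assert res.daily[0].per == 0.0

    def test_history_at_entrance_after_four_missed_crossings(self):
        # four missed crossings and 9.21 unwashed minutes since the wash
        zones = hr.ZoneTable([room("A"), room("B")])
        s = 552.6  # 9.21 min
        events = [
            hr.HygieneEvent(ts(0), "s1", "zone_entry", "A"),
            hr.HygieneEvent(ts(0), "s1", "handwash", "A"),
            hr.HygieneEvent(ts(40), "s1", "zone_exit", "A"),
            hr.HygieneEvent(ts(160), "s1", "zone_entry", "B"),
            hr.HygieneEvent(ts(220), "s1", "zone_exit", "B"),
            hr.HygieneEvent(ts(s), "s1", "zone_entry", "B"),
            hr.HygieneEvent(ts(s + 60), "s1", "zone_exit", "B"),
        ]
        res = build_and_replay(events, zones)
        last = res.entrances[-1]
        assert last.n_missed_before == 4
        assert last.history_at_entry == pytest.approx(13.21)

    def test_day_attribution_and_cross_midnight_state(self):
        # entrance at 23:55 belongs to day 1; state persists into day 2
        zones = hr.ZoneTable([room("A")])
        t_night = pd.Timestamp("2017-10-10T23:55:00")
        events = [
            hr.HygieneEvent(t_night - pd.Timedelta(minutes=10), "s1", "handwash", ""),
            hr.HygieneEvent(t_night, "s1", "zone_entry", "A"),
            hr.HygieneEvent(t_night + pd.Timedelta(minutes=10), "s1", "zone_exit", "A"),
            hr.HygieneEvent(t_night + pd.Timedelta(minutes=30), "s1", "zone_entry", "A"),
            hr.HygieneEvent(t_night + pd.Timedelta(minutes=40), "s1", "zone_exit", "A"),
        ]
        res = build_and_replay(events, zones)
        days = sorted(m.day.isoformat() for m in res.daily)
        assert days == ["2017-10-10", "2017-10-11"]
        rec2 = [m for m in res.daily if m.day.isoformat() == "2017-10-11"][0].entrances[0]
        assert rec2.n_missed_before == 3  # chain carried across midnight

    def test_room_exposure_from_worked_example_aggregates(self):
        # direct Eq-style recomputation from the reference per-entrance inputs
        def rec(inside, uniq, missed, outside):
            h = missed + outside
            return hr.EntranceRecord(
                "1104", "s", T0.date(), ts(0), ts(60), None, False,
                h, uniq, missed, inside, h * uniq, outside,
            )

        day1 = [rec(0.03, 1, 1, 5.68), rec(0.93, 3, 4, 9.21), rec(0.05, 1, 1, 1.55)]
        day2 = [
            rec(3.6, 1, 2, 20.2), rec(5.65, 2, 3, 37.38), rec(1.16, 2, 3, 53.05),
            rec(3.57, 5, 19, 71.6), rec(2.95, 2, 5, 13.92),
        ]
        assert hr.room_exposure(day1) == pytest.approx(37.1838)
        assert hr.room_exposure(day2) == pytest.approx(2395.088)
        assert hr.room_exposure([]) == 0.0


class TestInvariantsOnSimulatedLogs:
    def test_per_nonnegative_and_reset_invariant(self, small_sim):
        zones = small_sim.scenario.zone_table()
        res = build_and_replay(small_sim.events, zones)
        for m in res.daily:
            assert m.per >= 0.0
            assert 0.0 <= m.ecr <= 100.0
        for e in res.entrances:
            if e.compliant:
                assert e.entrance_risk == 0.0 and e.per_contribution == 0.0
            assert 0.0 <= e.unwashed_in_room <= (
                (e.t_ex - e.t_en).total_seconds() / SECONDS_PER_MINUTE
            ) + 1e-9

    def test_alpha_scaling_doubles_per(self, small_sim):
        # miss increments carry the zone's alpha, so scaling alpha alone
        # doubles every H term (misses and dwell alike)
        zones1 = small_sim.scenario.zone_table(alpha=1.0)
        zones2 = zones1.with_scaled_alpha(2.0)
        r1 = build_and_replay(small_sim.events, zones1)
        r2 = build_and_replay(small_sim.events, zones2)
        per1 = {(m.room_id, m.day): m.per for m in r1.daily}
        per2 = {(m.room_id, m.day): m.per for m in r2.daily}
        assert set(per1) == set(per2)
        for k in per1:
            # H doubles and unwashed time is unchanged -> PER doubles
            assert per2[k] == pytest.approx(2.0 * per1[k])

    def test_zero_alpha_zeroes_per(self, small_sim):
        zones0 = small_sim.scenario.zone_table(alpha=0.0)
        res = build_and_replay(small_sim.events, zones0)
        assert all(m.per == 0.0 for m in res.daily)

    def test_incremental_state_matches_bruteforce(self, small_sim):
        zones = small_sim.scenario.zone_table()
        visits = hr.sessionize(small_sim.events, zones)
        res = hr.compute_metrics(visits, zones, PARAMS)
        assert len(res.entrances) > 10
        for e in res.entrances:
            h, uniq, missed, risk = bruteforce.state_at_entrance(
                visits[e.staff_id], e.t_en, e.room_id, zones, PARAMS
            )
            assert e.history_at_entry == pytest.approx(h)
            assert e.n_unique_rooms == uniq
            assert e.n_missed_before == missed
            assert e.entrance_risk == pytest.approx(risk)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    extra_at=st.floats(min_value=1.0, max_value=18.0),
    extra_len=st.floats(min_value=0.5, max_value=1.5),
)
def test_inserted_missed_opportunity_never_decreases_risk(extra_at, extra_len):
    """An extra unwashed room visit before an entrance can only raise R there."""
    events, zones = chain_log()
    base = build_and_replay(events, zones)
    r_base = [e for e in base.entrances if e.room_id == "B"][0].entrance_risk

    extra = list(events) + [
        hr.HygieneEvent(ts(extra_at * 60), "s1", "zone_entry", "A"),
        hr.HygieneEvent(ts((extra_at + extra_len) * 60), "s1", "zone_exit", "A"),
    ]
    res = build_and_replay(extra, zones)
    r_new = [e for e in res.entrances if e.room_id == "B"][-1].entrance_risk
    assert r_new >= r_base - 1e-9


def test_load_config_round_trip(tmp_path):
    p = tmp_path / "params.toml"
    p.write_text(
        "t_c_seconds = 20\nt_p_seconds = 90\nmiss_increment = 0.5\nhallway_risk_factor = 0.2\n"
    )
    params, hallway = hr.load_config(p)
    assert params.t_c_seconds == 20 and params.t_p_seconds == 90
    assert params.miss_increment == 0.5 and hallway == 0.2
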