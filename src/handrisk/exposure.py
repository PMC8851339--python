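"""Patient exposure risk (PER) and entrance compliance rate (ECR).

The model replays each worker's sessionized timeline through four repeating
zones — out, entrance, in, exit — and maintains two pieces of state per
worker:

* ``H`` (history): accumulated risk since the last handwash.  Every missed
  crossing of a patient-room boundary adds ``alpha_zone * miss_increment``
  risk units; every minute spent in any zone without washing adds
  ``alpha_zone`` risk units per minute.  Any wash resets H to 0.
* ``l`` (visited rooms): the set of patient rooms crossed non-compliantly
  since the last wash (including the room currently being entered).  A wash
  empties the set.

A crossing is *compliant* when some wash falls within ``t_c`` seconds before
to ``t_p`` seconds after it; a wash shortly before a crossing therefore also
covers the case where exiting one room and entering the next are served by a
single wash (combined moments 4 and 1).

At each non-compliant entrance into a patient room the entering worker
carries risk ``R = H * |l|``, and the patient in that room is exposed for the
time the worker then spends inside unwashed.  Per room and calendar day,

    PER = sum_j  unwashed_in_room_j * R_j         (risk units, minutes-based)
    ECR = 100 * compliant entrances / entrances   (percent)

H mixes dimensionless missed-crossing increments with minutes of unwashed
dwell; the worked-example magnitudes are only reproducible with that unit
convention (miss_increment = 1 per missed crossing, durations in minutes),
which is therefore the default.
"""

from __future__ import annotations

import logging
import math
import tomllib
from bisect import bisect_left
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .event_model import Visit, ZoneConfig, ZoneTable

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0


class MetricParams(BaseModel):
    """Tunable constants of the exposure model.

    ``t_c_seconds`` / ``t_p_seconds`` are the grace windows before/after a
    zone crossing within which a wash counts as compliant for that crossing.
    The monitoring literature does not fix them; 30 s / 60 s are this
    package's defaults and both are ordinary config keys so a deployment can
    calibrate them.  ``miss_increment`` is the risk added to H per missed
    crossing (before the zone's α multiplier).
    """

    t_c_seconds: float = Field(default=30.0, ge=0)
    t_p_seconds: float = Field(default=60.0, ge=0)
    miss_increment: float = Field(default=1.0, ge=0)

    model_config = {"frozen": True}


def load_config(path: str | Path) -> tuple[MetricParams, float]:
    """Read the TOML config; returns (params, hallway_risk_factor)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    hallway = float(raw.pop("hallway_risk_factor", 1.0))
    params = MetricParams(
        **{k: raw[k] for k in ("t_c_seconds", "t_p_seconds", "miss_increment") if k in raw}
    )
    return params, hallway


@dataclass
class StaffState:
    """A worker's running contamination state."""

    staff_id: str
    history: float = 0.0
    visited_rooms: set[str] = field(default_factory=set)
    last_wash_time: pd.Timestamp | None = None
    n_missed_since_wash: int = 0

    def reset(self, wash_time: pd.Timestamp | None = None) -> None:
        self.history = 0.0
        self.visited_rooms = set()
        self.n_missed_since_wash = 0
        if wash_time is not None:
            self.last_wash_time = wash_time


@dataclass(frozen=True)
class EntranceRecord:
    """Audit record for one entry into a patient room."""

    room_id: str
    staff_id: str
    day: date
    t_en: pd.Timestamp
    t_ex: pd.Timestamp
    t_w: pd.Timestamp | None
    compliant: bool
    history_at_entry: float
    n_unique_rooms: int
    n_missed_before: int
    unwashed_in_room: float  # minutes
    entrance_risk: float
    minutes_outside_since_wash: float

    @property
    def per_contribution(self) -> float:
        return self.unwashed_in_room * self.entrance_risk


@dataclass(frozen=True)
class DailyRoomMetrics:
    """Per room, per calendar day: entrance counts, ECR and PER."""

    room_id: str
    day: date
    n_entrances: int
    n_compliant: int
    ecr: float
    per: float
    entrances: tuple[EntranceRecord, ...]


def classify_crossing(
    crossing_time: pd.Timestamp,
    wash_times: Sequence[pd.Timestamp],
    params: MetricParams,
) -> tuple[bool, pd.Timestamp | None]:
    """Is a zone crossing compliant, and which wash makes it so?

    Compliant iff some wash lies in ``[t - t_c, t + t_p]``; returns the
    earliest such wash.  A wash within ``t_c`` before the crossing is the
    combined-moments case (one wash serving a room exit and the next
    entrance), which this window covers without special-casing.
    """
    lo = crossing_time - pd.Timedelta(seconds=params.t_c_seconds)
    hi = crossing_time + pd.Timedelta(seconds=params.t_p_seconds)
    i = bisect_left(wash_times, lo)
    if i < len(wash_times) and wash_times[i] <= hi:
        return True, wash_times[i]
    return False, None


def update_history_crossing(
    state: StaffState, zone: ZoneConfig, compliant: bool, params: MetricParams
) -> StaffState:
    """Apply an entrance/exit crossing of *zone* to the worker state.

    A compliant crossing resets history and the visited-room set.  A missed
    patient-room crossing adds ``alpha * miss_increment`` to H and puts the
    room into ``l`` — on entry as well as on exit: the worker imports the
    accumulated contamination into the room and exports the room's agents on
    leaving, and only this both-sided membership reproduces the worked
    example's unique-room counts.
    """
    if compliant:
        state.reset()
    else:
        state.history += zone.risk_factor * params.miss_increment
        state.n_missed_since_wash += 1
        if zone.zone_class == "patient_room":
            state.visited_rooms.add(zone.zone_id)
    return state


def update_history_dwell(
    state: StaffState, visit: Visit, zone: ZoneConfig, params: MetricParams
) -> StaffState:
    """Accrue unwashed dwell time of *visit* (any zone class) into H.

    Each wash inside the visit resets the state; risk then accrues at
    ``alpha`` per minute from the last wash (or the visit start) to the exit.
    """
    start = visit.t_enter
    for w in visit.wash_times:
        state.reset(wash_time=w)
        start = w
    state.history += zone.risk_factor * (
        (visit.t_exit - start).total_seconds() / SECONDS_PER_MINUTE
    )
    return state


def entrance_risk(state: StaffState) -> float:
    """R = H × |l| at the moment of entering a room (after the crossing update)."""
    return state.history * len(state.visited_rooms)


def room_exposure(entrances: Iterable[EntranceRecord]) -> float:
    """PER for one room-day: Σ unwashed-in-room minutes × entrance risk."""
    return sum(e.per_contribution for e in entrances)


def entrance_compliance_rate(entrances: Sequence[EntranceRecord]) -> float:
    """ECR in percent; NaN for zero entrances (undefined, never 0 or 100)."""
    if len(entrances) == 0:
        return math.nan
    return 100.0 * sum(e.compliant for e in entrances) / len(entrances)


@dataclass
class MetricsResult:
    """All entrance records plus the per-(room, day) aggregation."""

    entrances: list[EntranceRecord]
    daily: list[DailyRoomMetrics]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "room_id": m.room_id,
                    "day": m.day.isoformat(),
                    "n_entrances": m.n_entrances,
                    "n_compliant": m.n_compliant,
                    "ecr": m.ecr,
                    "per": m.per,
                }
                for m in self.daily
            ],
            columns=["room_id", "day", "n_entrances", "n_compliant", "ecr", "per"],
        )

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "room_id": e.room_id,
                    "day": e.day.isoformat(),
                    "staff_id": e.staff_id,
                    "t_en": e.t_en.isoformat(),
                    "t_ex": e.t_ex.isoformat(),
                    "compliant": e.compliant,
                    "history_at_entry": e.history_at_entry,
                    "n_unique_rooms": e.n_unique_rooms,
                    "n_missed_before": e.n_missed_before,
                    "unwashed_in_room": e.unwashed_in_room,
                    "entrance_risk": e.entrance_risk,
                    "minutes_outside_since_wash": e.minutes_outside_since_wash,
                }
                for e in self.entrances
            ],
            columns=[
                "room_id", "day", "staff_id", "t_en", "t_ex", "compliant",
                "history_at_entry", "n_unique_rooms", "n_missed_before",
                "unwashed_in_room", "entrance_risk", "minutes_outside_since_wash",
            ],
        )


def compute_metrics(
    visits_by_staff: dict[str, list[Visit]],
    zones: ZoneTable,
    params: MetricParams | None = None,
) -> MetricsResult:
    """Replay all staff timelines and aggregate PER/ECR per room per day.

    One chronological pass per staff interleaves crossing classification,
    crossing updates and dwell accrual.  Worker state persists across
    calendar-day boundaries; an entrance belongs to the local calendar day of
    its entry time, and visits spanning midnight are not split.
    """
    params = params or MetricParams()
    records: list[EntranceRecord] = []

    for staff_id, visits in visits_by_staff.items():
        if not visits:
            continue
        state = StaffState(staff_id)
        all_washes: list[pd.Timestamp] = sorted(
            w for v in visits for w in v.wash_times
        )
        t_origin = visits[0].t_enter

        for visit in visits:
            zone = zones.get(visit.zone_id) if not visit.implicit else zones.out_zone
            if zone.zone_class != "patient_room":
                update_history_dwell(state, visit, zone, params)
                continue

            # --- entrance crossing -------------------------------------
            compliant_en, eff_wash = classify_crossing(visit.t_enter, all_washes, params)
            update_history_crossing(state, zone, compliant_en, params)
            # latest wash strictly before entry, for the outside-time audit
            i = bisect_left(all_washes, visit.t_enter)
            last_wash_before = all_washes[i - 1] if i > 0 else None
            outside_ref = last_wash_before if last_wash_before is not None else t_origin
            minutes_outside = (
                (visit.t_enter - outside_ref).total_seconds() / SECONDS_PER_MINUTE
            )

            if compliant_en:
                records.append(
                    EntranceRecord(
                        room_id=visit.zone_id,
                        staff_id=staff_id,
                        day=visit.t_enter.date(),
                        t_en=visit.t_enter,
                        t_ex=visit.t_exit,
                        t_w=eff_wash,
                        compliant=True,
                        history_at_entry=0.0,
                        n_unique_rooms=0,
                        n_missed_before=0,
                        unwashed_in_room=0.0,
                        entrance_risk=0.0,
                        minutes_outside_since_wash=minutes_outside,
                    )
                )
            else:
                inside = [w for w in visit.wash_times if w > visit.t_enter]
                first_inside = inside[0] if inside else None
                unwashed_end = first_inside if first_inside is not None else visit.t_exit
                records.append(
                    EntranceRecord(
                        room_id=visit.zone_id,
                        staff_id=staff_id,
                        day=visit.t_enter.date(),
                        t_en=visit.t_enter,
                        t_ex=visit.t_exit,
                        t_w=first_inside,
                        compliant=False,
                        history_at_entry=state.history,
                        n_unique_rooms=len(state.visited_rooms),
                        n_missed_before=state.n_missed_since_wash,
                        unwashed_in_room=(
                            (unwashed_end - visit.t_enter).total_seconds()
                            / SECONDS_PER_MINUTE
                        ),
                        entrance_risk=entrance_risk(state),
                        minutes_outside_since_wash=minutes_outside,
                    )
                )

            # --- in-room dwell and exit crossing -----------------------
            update_history_dwell(state, visit, zone, params)
            compliant_ex, _ = classify_crossing(visit.t_exit, all_washes, params)
            update_history_crossing(state, zone, compliant_ex, params)

    records.sort(key=lambda r: (r.room_id, r.day, r.t_en))
    daily: list[DailyRoomMetrics] = []
    by_key: dict[tuple[str, date], list[EntranceRecord]] = {}
    for r in records:
        by_key.setdefault((r.room_id, r.day), []).append(r)
    for (room_id, day), recs in sorted(by_key.items()):
        daily.append(
            DailyRoomMetrics(
                room_id=room_id,
                day=day,
                n_entrances=len(recs),
                n_compliant=sum(r.compliant for r in recs),
                ecr=entrance_compliance_rate(recs),
                per=room_exposure(recs),
                entrances=tuple(recs),
            )
        )
    return MetricsResult(entrances=records, daily=daily)
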