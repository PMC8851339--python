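"""Badge event-log model: reading, validation, and sessionization.

An electronic hand-hygiene monitoring system emits one record per badge
crossing of a room boundary (``zone_entry`` / ``zone_exit``) and one per
dispenser use (``handwash``).  This module turns such a log into per-staff
ordered sequences of :class:`Visit` intervals — explicit patient-room (or
other configured-zone) stays plus implicit hallway ("out") stays filling the
gaps — on which the exposure metric operates.

Real badge logs are lossy: entries without exits and vice versa occur.
Following the repair-not-reject policy, unclosed visits are auto-closed and
orphan exits get a synthesized entry; every repair is logged as a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("zone_entry", "zone_exit", "handwash")

#: Tie-break order for events sharing a timestamp: an entry precedes a wash
#: precedes an exit within the same second.  (The monitoring hardware's own
#: resolution rule is unknown; this is a documented convention.)
_TYPE_ORDER = {"zone_entry": 0, "handwash": 1, "zone_exit": 2}

EVENT_LOG_HEADER = ["timestamp", "staff_id", "event_type", "zone_id"]
ZONE_CONFIG_HEADER = ["zone_id", "zone_class", "risk_factor"]

ZONE_CLASSES = ("patient_room", "hallway", "utility", "other")

#: zone_id used for the implicit out-of-room zone.
OUT_ZONE_ID = ""


class EventLogError(ValueError):
    """Raised for schema violations; carries per-row errors with line numbers."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


@dataclass(frozen=True)
class HygieneEvent:
    """One time-stamped badge or dispenser record."""

    timestamp: pd.Timestamp
    staff_id: str
    event_type: str
    zone_id: str = ""

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise EventLogError(f"unknown event_type {self.event_type!r}")
        if self.event_type in ("zone_entry", "zone_exit") and not self.zone_id:
            raise EventLogError(f"{self.event_type} requires a non-empty zone_id")
        if pd.isna(self.timestamp):
            raise EventLogError("timestamp must be finite")


@dataclass(frozen=True)
class ZoneConfig:
    """Static description of a zone: its class and risk factor α (≥ 0)."""

    zone_id: str
    zone_class: str
    risk_factor: float = 1.0

    def __post_init__(self):
        if self.zone_class not in ZONE_CLASSES:
            raise EventLogError(f"unknown zone_class {self.zone_class!r}")
        if not self.risk_factor >= 0:
            raise EventLogError("risk_factor must be >= 0")


class ZoneTable:
    """Lookup table of :class:`ZoneConfig` with an implicit hallway zone.

    Any inter-room gap is attributed to a single "out" zone of class
    ``hallway``; its risk factor defaults to 1.0 and can be overridden either
    by configuring a zone of class ``hallway`` or via *hallway_risk_factor*.
    """

    def __init__(self, zones: Iterable[ZoneConfig], hallway_risk_factor: float | None = None):
        self._zones: dict[str, ZoneConfig] = {}
        for z in zones:
            if z.zone_id in self._zones:
                raise EventLogError(f"duplicate zone_id {z.zone_id!r}")
            self._zones[z.zone_id] = z
        hallway = next(
            (z for z in self._zones.values() if z.zone_class == "hallway"), None
        )
        alpha = (
            hallway_risk_factor
            if hallway_risk_factor is not None
            else (hallway.risk_factor if hallway else 1.0)
        )
        self.out_zone = ZoneConfig(OUT_ZONE_ID, "hallway", alpha)

    def __contains__(self, zone_id: str) -> bool:
        return zone_id in self._zones

    def __iter__(self):
        return iter(self._zones.values())

    def get(self, zone_id: str) -> ZoneConfig:
        """Config for *zone_id*; unknown ids map to class ``other`` with α=1."""
        if zone_id == OUT_ZONE_ID:
            return self.out_zone
        cfg = self._zones.get(zone_id)
        if cfg is None:
            logger.warning("unknown zone_id %r: treating as class 'other', alpha=1", zone_id)
            return ZoneConfig(zone_id, "other", 1.0)
        return cfg

    def is_patient_room(self, zone_id: str) -> bool:
        cfg = self._zones.get(zone_id)
        return cfg is not None and cfg.zone_class == "patient_room"

    def with_scaled_alpha(self, factor: float) -> "ZoneTable":
        """A copy with every risk factor multiplied by *factor*."""
        return ZoneTable(
            [replace(z, risk_factor=z.risk_factor * factor) for z in self._zones.values()],
            hallway_risk_factor=self.out_zone.risk_factor * factor,
        )


@dataclass
class Visit:
    """One contiguous stay of a staff member in a zone.

    ``implicit`` marks an out-of-room gap reconstructed between two explicit
    zone visits (no badge events delimit it directly).
    """

    staff_id: str
    zone_id: str
    t_enter: pd.Timestamp
    t_exit: pd.Timestamp
    wash_times: list[pd.Timestamp] = field(default_factory=list)
    implicit: bool = False

    def __post_init__(self):
        if not self.t_enter < self.t_exit:
            raise EventLogError(
                f"visit must have t_enter < t_exit (got {self.t_enter} .. {self.t_exit})"
            )

    @property
    def duration_minutes(self) -> float:
        return (self.t_exit - self.t_enter).total_seconds() / 60.0


def _sort_key(ev: HygieneEvent):
    return (ev.staff_id, ev.timestamp, _TYPE_ORDER[ev.event_type])


def sort_events(events: Iterable[HygieneEvent]) -> list[HygieneEvent]:
    return sorted(events, key=_sort_key)


def read_event_log(path: str | Path, on_error: str = "raise") -> list[HygieneEvent]:
    """Read and validate an event-log CSV.

    The file must carry the exact header ``timestamp,staff_id,event_type,zone_id``
    with ISO-8601 timestamps (fractional seconds permitted).  Returns events
    sorted by (staff_id, timestamp).  Malformed rows are reported with their
    line number; ``on_error='raise'`` aborts, ``'skip'`` drops them (collected
    in the log).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_LOG_HEADER:
        raise EventLogError(
            f"bad header {list(df.columns)}; expected {EVENT_LOG_HEADER}"
        )
    events: list[HygieneEvent] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        ts = pd.to_datetime(row.timestamp, format="ISO8601", errors="coerce")
        if pd.isna(ts):
            errors.append(f"line {line}: unparseable timestamp {row.timestamp!r}")
            continue
        if row.event_type not in EVENT_TYPES:
            errors.append(f"line {line}: unknown event_type {row.event_type!r}")
            continue
        if row.event_type in ("zone_entry", "zone_exit") and not row.zone_id:
            errors.append(f"line {line}: {row.event_type} with empty zone_id")
            continue
        events.append(HygieneEvent(ts, str(row.staff_id), row.event_type, str(row.zone_id)))
    if errors:
        if on_error == "raise":
            raise EventLogError(
                f"{len(errors)} malformed row(s): " + "; ".join(errors), errors
            )
        for e in errors:
            logger.warning("skipping %s", e)
    return sort_events(events)


def write_event_log(events: Iterable[HygieneEvent], path: str | Path) -> None:
    """Write events as the standard CSV (chronologically sorted per staff)."""
    rows = [
        {
            "timestamp": ev.timestamp.isoformat(),
            "staff_id": ev.staff_id,
            "event_type": ev.event_type,
            "zone_id": ev.zone_id,
        }
        for ev in sort_events(events)
    ]
    pd.DataFrame(rows, columns=EVENT_LOG_HEADER).to_csv(path, index=False)


def read_zone_config(path: str | Path, hallway_risk_factor: float | None = None) -> ZoneTable:
    """Read the zone configuration CSV (``zone_id,zone_class,risk_factor``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"zone_id": str})
    if list(df.columns) != ZONE_CONFIG_HEADER:
        raise EventLogError(f"bad header {list(df.columns)}; expected {ZONE_CONFIG_HEADER}")
    zones = [
        ZoneConfig(str(r.zone_id), str(r.zone_class), float(r.risk_factor))
        for r in df.itertuples(index=False)
    ]
    return ZoneTable(zones, hallway_risk_factor=hallway_risk_factor)


def write_zone_config(zones: ZoneTable, path: str | Path) -> None:
    rows = [
        {"zone_id": z.zone_id, "zone_class": z.zone_class, "risk_factor": z.risk_factor}
        for z in zones
    ]
    pd.DataFrame(rows, columns=ZONE_CONFIG_HEADER).to_csv(path, index=False)


def sessionize(
    events: Sequence[HygieneEvent], zones: ZoneTable
) -> dict[str, list[Visit]]:
    """Reconstruct per-staff ordered visit sequences from raw crossings.

    For each staff the result alternates explicit zone visits with implicit
    out-visits covering the gaps, so the union of intervals spans every event
    of that staff.  Washes are attached to the visit whose interval contains
    them (boundary washes belong to the bounding explicit visit; washes
    strictly inside a gap to the implicit out-visit).

    Repairs (logged as warnings):

    * second ``zone_entry`` with no intervening exit → previous visit is
      auto-closed at the new entry time;
    * ``zone_exit`` with no open visit → an entry is synthesized at the
      staff's previous event time;
    * open visit at end of log → closed at the staff's last event time.

    Zero-length visits arising from repairs are dropped.
    """
    out: dict[str, list[Visit]] = {}
    ordered = sort_events(events)
    by_staff: dict[str, list[HygieneEvent]] = {}
    for ev in ordered:
        by_staff.setdefault(ev.staff_id, []).append(ev)

    for staff_id, evs in by_staff.items():
        room_visits: list[Visit] = []
        washes: list[pd.Timestamp] = []
        open_zone: str | None = None
        open_t: pd.Timestamp | None = None
        prev_t: pd.Timestamp | None = None

        def close(t_exit: pd.Timestamp):
            nonlocal open_zone, open_t
            if open_t is not None and open_t < t_exit:
                room_visits.append(Visit(staff_id, open_zone, open_t, t_exit))
            elif open_t is not None:
                logger.warning(
                    "staff %s: dropping zero-length visit to %s at %s",
                    staff_id, open_zone, open_t,
                )
            open_zone = open_t = None

        for ev in evs:
            if ev.event_type == "handwash":
                washes.append(ev.timestamp)
            elif ev.event_type == "zone_entry":
                if open_zone is not None:
                    logger.warning(
                        "staff %s: entry to %s at %s before exiting %s; auto-closing",
                        staff_id, ev.zone_id, ev.timestamp, open_zone,
                    )
                    close(ev.timestamp)
                open_zone, open_t = ev.zone_id, ev.timestamp
            else:  # zone_exit
                if open_zone is None:
                    synth = prev_t if prev_t is not None else ev.timestamp
                    logger.warning(
                        "staff %s: exit from %s at %s without entry; synthesizing entry at %s",
                        staff_id, ev.zone_id, ev.timestamp, synth,
                    )
                    open_zone, open_t = ev.zone_id, synth
                elif open_zone != ev.zone_id:
                    logger.warning(
                        "staff %s: exit from %s at %s while inside %s; closing open visit",
                        staff_id, ev.zone_id, ev.timestamp, open_zone,
                    )
                close(ev.timestamp)
            prev_t = ev.timestamp
        if open_zone is not None:
            logger.warning(
                "staff %s: visit to %s still open at end of log; auto-closing at %s",
                staff_id, open_zone, prev_t,
            )
            close(prev_t)

        visits = _interleave_out_visits(staff_id, room_visits, evs)
        _attach_washes(visits, washes)
        out[staff_id] = visits
    return out


def _interleave_out_visits(
    staff_id: str, room_visits: list[Visit], evs: list[HygieneEvent]
) -> list[Visit]:
    first_t = evs[0].timestamp
    last_t = evs[-1].timestamp
    visits: list[Visit] = []
    cursor = first_t
    for v in room_visits:
        if cursor < v.t_enter:
            visits.append(Visit(staff_id, OUT_ZONE_ID, cursor, v.t_enter, implicit=True))
        visits.append(v)
        cursor = v.t_exit
    if cursor < last_t:
        visits.append(Visit(staff_id, OUT_ZONE_ID, cursor, last_t, implicit=True))
    return visits


def _attach_washes(visits: list[Visit], washes: list[pd.Timestamp]) -> None:
    for w in washes:
        target = None
        for v in visits:
            if v.implicit:
                if v.t_enter < w < v.t_exit:
                    # could still belong to an adjacent explicit visit boundary,
                    # but boundaries of implicit visits coincide with explicit
                    # ones, which are checked with inclusive bounds first below
                    target = target or v
            elif v.t_enter <= w <= v.t_exit:
                target = v
                break
        if target is None and visits:
            # wash at the very edge of the timeline (first/last event)
            target = visits[0] if w <= visits[0].t_enter else visits[-1]
        if target is not None:
            target.wash_times.append(w)
    for v in visits:
        v.wash_times.sort()


def visits_to_events(visits_by_staff: dict[str, list[Visit]]) -> list[HygieneEvent]:
    """Inverse of :func:`sessionize` (implicit out-visits emit no crossings)."""
    events: list[HygieneEvent] = []
    for staff_id, visits in visits_by_staff.items():
        for v in visits:
            if not v.implicit:
                events.append(HygieneEvent(v.t_enter, staff_id, "zone_entry", v.zone_id))
                events.append(HygieneEvent(v.t_exit, staff_id, "zone_exit", v.zone_id))
            for w in v.wash_times:
                zone = v.zone_id if not v.implicit else ""
                events.append(HygieneEvent(w, staff_id, "handwash", zone))
    return sort_events(events)
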