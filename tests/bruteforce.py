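"""Independent brute-force recomputation of the worker state at an entrance.

Deliberately structured unlike the incremental replay in handrisk.exposure:
for each entrance it rescans the staff's whole past, finds the last
state-clearing event (any wash, or any compliant crossing) directly from the
raw wash list, and recomputes history, the visited-room set and the missed
count in closed form over the interval since that reset.
"""

from __future__ import annotations

from bisect import bisect_left

import pandas as pd

from handrisk.event_model import Visit, ZoneTable
from handrisk.exposure import MetricParams, SECONDS_PER_MINUTE


def _compliant(t, washes, params):
    lo = t - pd.Timedelta(seconds=params.t_c_seconds)
    hi = t + pd.Timedelta(seconds=params.t_p_seconds)
    i = bisect_left(washes, lo)
    return i < len(washes) and washes[i] <= hi


def _crossings(visits, zones):
    """All patient-room boundary crossings of one staff, in time order."""
    out = []
    for v in visits:
        if not v.implicit and zones.get(v.zone_id).zone_class == "patient_room":
            out.append((v.t_enter, "en", v.zone_id))
            out.append((v.t_exit, "ex", v.zone_id))
    return sorted(out)


def _alpha_weighted_minutes(visits, zones, t0, t1):
    """Integral of the occupied zone's risk factor over (t0, t1)."""
    total = 0.0
    for v in visits:
        lo, hi = max(v.t_enter, t0), min(v.t_exit, t1)
        if lo < hi:
            zone = zones.out_zone if v.implicit else zones.get(v.zone_id)
            total += zone.risk_factor * (hi - lo).total_seconds() / SECONDS_PER_MINUTE
    return total


def state_at_entrance(
    visits: list[Visit],
    t_entry: pd.Timestamp,
    room_id: str,
    zones: ZoneTable,
    params: MetricParams,
):
    """(history, unique_rooms, n_missed, risk) just after the entry crossing."""
    washes = sorted(w for v in visits for w in v.wash_times)
    crossings = _crossings(visits, zones)

    if _compliant(t_entry, washes, params):
        return 0.0, 0, 0, 0.0

    resets = [w for w in washes if w < t_entry]
    resets += [t for (t, _, _) in crossings if t < t_entry and _compliant(t, washes, params)]
    t0 = max(resets) if resets else visits[0].t_enter

    missed = [
        (t, zid)
        for (t, _, zid) in crossings
        if t0 < t <= t_entry and not _compliant(t, washes, params)
    ]
    rooms = {zid for (_, zid) in missed}
    n_missed = len(missed)
    history = sum(
        zones.get(zid).risk_factor * params.miss_increment for (_, zid) in missed
    ) + _alpha_weighted_minutes(visits, zones, t0, t_entry)
    return history, len(rooms), n_missed, history * len(rooms)
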