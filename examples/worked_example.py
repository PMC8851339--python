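"""Replay the two-day worked example for room 1104.

Builds the engineered badge log, sessionizes it, and prints per-day ECR and
PER together with the per-entrance breakdown of the non-compliant workers.
The two days illustrate the core point of the exposure metric: day 2 has the
*better* compliance rate (80% vs 57%) yet a patient exposure risk two orders
of magnitude higher, because the unwashed workers arrived with long missed-
opportunity chains and lingered inside.
"""

import handrisk as hr

zones = hr.fixture_zone_table()
events = hr.fixture_worked_example()
visits = hr.sessionize(events, zones)
result = hr.compute_metrics(visits, zones)

for metrics in result.daily:
    if metrics.room_id != "1104":
        continue
    print(f"\nroom {metrics.room_id}  {metrics.day}:  "
          f"{metrics.n_entrances} entrances, {metrics.n_compliant} compliant  "
          f"ECR={metrics.ecr:.2f}%  PER={metrics.per:.2f}")
    print("  staff  missed  rooms  outside(min)  inside(min)      R   contribution")
    for e in metrics.entrances:
        if e.compliant:
            continue
        print(f"  {e.staff_id:>5}  {e.n_missed_before:>6}  {e.n_unique_rooms:>5}"
              f"  {e.minutes_outside_since_wash:>12.2f}  {e.unwashed_in_room:>11.2f}"
              f"  {e.entrance_risk:>7.2f}  {e.per_contribution:>12.2f}")

print("\nPER sums unwashed-inside minutes x entering worker's risk R = H x |rooms|;")
print("a high ECR day can still expose the patient far more than a low ECR day.")
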