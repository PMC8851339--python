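"""Descriptive statistics of missed hand-hygiene chains on a simulated ward.

Shows the analyses that motivate the exposure metric: how often unwashed
entrances arrive at the end of a multi-miss chain, how many distinct rooms
those chains touch, and how long workers were outside (unwashed) before
entering.
"""

import handrisk as hr

scenario = hr.SimScenario(
    n_staff=20, n_days=10, compliance_prob=0.55, visits_per_staff_day=6.0, seed=7
)
sim = hr.simulate(scenario)
zones = scenario.zone_table()
result = hr.compute_metrics(hr.sessionize(sim.events, zones), zones)

chains = hr.chain_analysis(result)
print(f"{chains.n_noncompliant} non-compliant entrances")
print(f"fraction at the end of a chain (>=2 misses): {chains.frac_chain_ge2:.2%}")
print(f"fraction of >=2 chains confined to one room: {chains.frac_same_room_repeat:.2%}")

print("\nUnique rooms per chain (% of unwashed entrances):")
print(hr.unique_rooms_histogram(chains).round(2).to_string())

print("\nMinutes outside before an unwashed entrance (5-min bins, fraction):")
print(hr.time_outside_distribution(chains).round(3).to_string())

print("\nAverage unwashed in-room minutes per room per day:")
print(hr.unwashed_room_time_daily(result).round(2).to_string())
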