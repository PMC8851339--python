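"""Simulate a small ward and compare ECR with PER across room-days.

Generates one week of badge traffic for 12 nurses over 6 patient rooms at
60% per-opportunity compliance, computes the daily metrics, and reports the
Spearman correlation between PER and (100 - ECR).  A strong but imperfect
positive correlation is the expected picture: missed entrances drive both
quantities, but dwell times and chain structure decouple them.
"""

import handrisk as hr

scenario = hr.SimScenario(
    n_staff=12,
    room_ids=[f"11{i:02d}" for i in range(1, 7)],
    n_days=7,
    compliance_prob=0.6,
    visits_per_staff_day=6.0,
    seed=20171001,
)
sim = hr.simulate(scenario)
zones = scenario.zone_table()
result = hr.compute_metrics(hr.sessionize(sim.events, zones), zones)

df = result.metrics_frame()
print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

rc = hr.spearman(df["per"], 100.0 - df["ecr"])
print(f"\n{len(sim.events)} events, {len(df)} room-days, "
      f"empirical compliance {sim.empirical_compliance:.3f} (target 0.6)")
print(f"Spearman r between PER and (100-ECR): {rc.coefficient:.3f} "
      f"(n={rc.n}, p={rc.p_value:.2g})")
print("r well below 1 means compliance rate alone misranks exposure on some days.")
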