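# Methods

## Model

`handrisk` treats a worker's badge trace as an alternating sequence of
zones: out of any room ("out"), a room entrance ("en"), inside ("in"), and
the exit ("ex"). Entrances and exits of patient rooms are hand-hygiene
opportunities (the before-contact and after-contact moments of the
standard four-moment protocol; the aseptic-procedure and body-fluid moments
are not observable from badge data and are out of scope).

### Compliance window

A crossing at time *t* is compliant iff a wash exists in
`[t − t_c, t + t_p]`. The backward window `t_c` covers the combined-moment
case — washing at one room's exit and immediately entering the next room —
so consecutive opportunities served by one wash are not double-counted. The
forward window `t_p` tolerates washing shortly after entering. Neither
constant has a canonical value in the monitoring literature; the defaults
(`t_c = 30 s`, `t_p = 60 s`) are package choices exposed as mandatory
config keys (`t_c_seconds`, `t_p_seconds`) so a deployment can calibrate
them against its own dispenser placement.

### History and visited rooms

Each worker carries `H` (risk units) and a set `l` of rooms, both cleared
by every wash:

* a missed crossing of zone *z* adds `α_z · m` to `H` (miss increment
  `m = 1` by default) and, when *z* is a patient room, adds *z* to `l` —
  on entry (contamination imported into the room) and on exit
  (contamination exported from it). Membership on *both* missed crossings,
  including the entrance currently being scored, is the only rule
  consistent with the worked example's unique-room counts; it is a
  documented design choice where the narrative description alone is
  ambiguous.
* unwashed dwell in any zone adds `α_z · Δt` with `Δt` in **minutes**; a
  wash inside a zone resets the state and accrual restarts from the wash.

`H` therefore mixes a dimensionless miss count with minutes of unwashed
dwell. That unit mix is deliberate: the worked example's magnitudes
(e.g. `H = 4 + 9.21 = 13.21` after four missed crossings and 9.21 unwashed
minutes) are reproducible only under exactly this convention. `m` is
exposed should a user want to re-weight misses against minutes.

At a non-compliant entrance, after applying the entrance's own miss, the
worker's entering risk is `R = H · |l|`, and the entrance contributes
`R × (unwashed minutes inside)` to that room's daily PER, where the
unwashed time runs to the first in-room wash or, absent one, to the exit.
A compliant entrance contributes zero by definition — even when the
qualifying wash happens inside during the `t_p` grace, the wash is
considered "at entrance". ECR is the percentage of compliant entrances;
for a room-day with no entrances both quantities are reported missing,
never as 0 or 100.

The per-entrance miss count reported in the audit trail
(`n_missed_before`) is the chain length inclusive of the current entrance,
matching how the worked example tallies "missed opportunities".

### Aggregation conventions

An entrance belongs to the local calendar day of its entry time; visits
spanning midnight are not split (splitting would break PER's additivity
over entrances), and worker state persists across midnight — nothing about
contamination resets with the date. Risk factors `α_z` multiply both miss
increments and dwell, so scaling all `α` by a constant scales every `H`,
`R` and PER by the same constant, and `α = 0` forces PER = 0; these
linearity properties are asserted in the test suite.

## Event-log handling

Logs are CSV with header `timestamp,staff_id,event_type,zone_id`,
ISO-8601 timestamps (fractional seconds accepted — some printed durations
in the worked example, e.g. 9.21 min = 552.6 s, are not whole seconds).
Same-second ties are ordered entry < wash < exit; the hardware's own
resolution rule is unknown and this is a stated convention. Because real
badge logs are lossy, sessionization repairs rather than rejects: a second
entry with no intervening exit auto-closes the open visit, an orphan exit
synthesizes an entry at the previous event time, an unclosed visit is
closed at the staff's last event; every repair is logged. Gaps between
explicit visits become one implicit "out" visit whose risk factor is the
hallway's (config key `hallway_risk_factor`, default 1.0). Washes between
visits attach to the implicit out-visit. Crossings of configured
non-patient zones (utility, other) are not opportunities; those zones
contribute dwell at their own `α`. Unknown zone ids are treated as class
"other" with `α = 1` and a warning.

## Synthetic ward simulator

The simulator generates per-staff days of alternating hallway gaps and
room visits, with an independent Bernoulli wash decision per crossing;
planned washes are placed inside `[crossing − t_c/2, crossing + t_p/2]`.
Dwell draws are clipped below at 2 minutes so a wash placed for one
crossing can never wander into a neighbouring crossing's window; as a
result the generator's planned compliance flags coincide exactly with the
metric's classification, which the tests assert.

Defaults mirror the study setting the model was developed in: 10 single
patient rooms, 59 nurses, an 85-day observation period. Where no value is
reported the defaults are chosen once as field-plausible: per-opportunity
compliance 0.6 (hospital adherence spans roughly 5–89%; 0.6 keeps both
behaviours well represented), Poisson(4) room visits per staff-day
(consistent with the order of magnitude of unwashed entrances per day in
the motivating data), log-normal dwells — in-room median 2 min
(log-sd 0.8), out-of-room median 8 min (log-sd 1.3, putting ~36% of gaps
under 5 minutes and ~80% under 25, matching the reported skew). The
simulator emulates movement and washing behaviour only: no pathogen
dynamics, no activity types, no inter-staff correlation, no shift
structure beyond a start-of-shift wash. Passing tests on simulated wards
therefore validate the *computation*, not any epidemiological claim about
real wards.

`fixture_worked_example()` is a deterministic engineered log reproducing the
reference two-day worked example for room 1104: day 1 with 7 entrances
(ECR 57.14%), day 2 with 25 (ECR 80%), and per-entrance aggregates for the
non-compliant workers matching the printed table to two decimals. The
aggregates are realized as concrete timelines; the contract is on the
aggregates the metric re-extracts, not on the specific event placement.
Replaying it yields PER 37.1838 (day 1) and 2395.09 (day 2) against
printed values of 37.59 and 2388.24; the residual ~1% / ~0.3%
discrepancies are consistent with the table's inputs being rounded (and in
one case likely misprinted) at two decimals, since the printed output is
not exactly reachable from the printed inputs under any rounding of them.

## Statistics

Chain analysis, the unique-rooms histogram, per-room daily unwashed time
(total unwashed in-room minutes divided by the number of days in the
period) and the time-outside distribution (default 5-minute bins) are
direct tabulations of the entrance audit records; each is cross-checked in
the tests against an independent recount of the raw log. The Spearman
correlation is the Pearson correlation of average-rank vectors (scipy's
implementation), with the p-value from the large-sample t approximation on
n − 2 degrees of freedom; a constant vector yields a missing coefficient.

## Numerical and degenerate-input choices

Times are handled as nanosecond timestamps and converted to minutes only
at accrual, so no drift accumulates; PER is a plain float sum. Zero-length
visits produced by log repairs are dropped. Empty logs produce empty (not
failing) outputs. The comparison report applies `log10(PER + 1)` only at
reporting time; stored metrics are untransformed.

## Known limitations

Single-bed rooms only (no in-room localization, so no per-patient
attribution in shared rooms); no activity-type weighting; no credit
against prolonged contact after a compliant wash; exposure is attributed
to rooms, not to the patients occupying them. The incremental state
machine is verified against a brute-force from-scratch recomputation on
randomized simulated logs, but the model itself is a risk *proxy*: it has
not been validated against infection outcomes.
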