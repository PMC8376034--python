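# Methods

## What the toolkit models

A daily SMS reporting chain for routine immunization: facility health
workers summarise each vaccination session as a coded text; a *harvester*
stores every message; an *interpreter* resolves the sender's phone number
to a facility, decodes the letter+number tokens, and emits structured
session reports; a quality engine computes completeness, internal
consistency, wastage and supervision indicators; and an export layer rolls
the indicators into an aggregate `dataElement,orgUnit,period,value` table
of the kind national health-information platforms ingest. The sender's
phone number is the facility's identity, so phone uniqueness in the
registry is a hard invariant and phones are normalised (non-digits
stripped, a leading `234` country code mapped to local `0`) before lookup.

## The code table

The default table carries, per FS/OS message, 8 children-vaccinated fields
(BCG, OPV, Penta 1–3, measles, yellow fever, IPV — letters `a`–`h`),
6 doses-opened fields (letters `i`–`n`; pentavalent doses share one vial
code because Penta ships in single-dose vials while children are recorded
per dose number), and one conducted-sessions count (`o`) — 15 fields. The
WK message carries the planned weekly fixed-post and outreach counts. Only
the `a` = BCG-children and `f` = measles-children assignments are treated
as fixed conventions; the full table is a YAML/JSON configuration artifact
so any operational table can be dropped in, and tests pin only `a` and
`f`. Values are non-negative integers capped at 9999 (an out-of-range
issue beyond that); a duplicate letter within one message keeps the last
occurrence ("latest correction wins") with an issue recorded.

## Ingest semantics

* Session date = calendar date of receipt (the design is same-day
  reporting); late texts surface as timeliness problems rather than being
  silently re-dated. Timestamps are interpreted in one configured zone
  (UTC+01:00).
* Exact duplicates (same sender, text, day) collapse to the latest copy at
  harvest; *differing* same-day texts of one type are treated as
  corrections — the later supersedes, and the earlier is recorded as a
  `duplicate` reject whose detail names the superseding message, which is
  also the audit trail. One FS and one OS from the same facility on one
  day are both valid.
* Conservation: every input message ends as exactly one session report,
  weekly plan, or reject record; this is property-tested.

## Consistency states and flags

Per antigen within one report, with children `c` and doses opened `d`:
impossible (`c > d`, both present — includes the degenerate `d = 0` with
`c > 0`), high wastage (`(d − c)/d > 0.80`, threshold configurable),
consistent, or not evaluable (either value absent, or `d = 0` without
excess children). Absent never counts as zero — this is what prevents a
facility that texted only children counts from being flagged impossible.
The states are mutually exclusive by construction. An outreach report that
records zero doses opened for an antigen while showing any activity at all
earns an informational `ZERO_DOSES_OUTREACH` flag. Shared-vial pentavalent
doses are compared against the summed Penta 1–3 children.

Discrepancy summaries count a facility on its *first* flagged session
(≥ 1 rule, stated in the output metadata) and report two denominators —
facilities that ever reported, and facilities included — because
administrative summaries legitimately switch between them. Display
percentages round to the nearest integer. Expected report counts use ISO
weeks, weekdays only (no weekend sessions); a window's length in weeks is
its weekday count divided by 5.

Trend summaries on the daily dose/children series are descriptive only: an
ordinary-least-squares slope and its standard error, with "no trend"
meaning the slope lies within two standard errors of zero. No hypothesis
test is claimed.

## The simulator

`simulate_fleet` generates a deterministic stream from a single seeded
numpy generator consumed in documented order (chronological; per facility
fixed-post before outreach; Monday weekly plans; then supervision).
Defaults describe the pilot-like fleet: 50 facilities split ~25:30 across
two districts; 6% hospitals (5 fixed-post sessions/week), 12% urban PHCs
(2/week), 82% primary facilities (1/week, session day cycled Tuesday
first); one planned outreach session per facility; weekday reporting
probabilities peaking on Tuesday (0.50/0.70/0.55/0.45/0.35 Mon–Fri, zero
on weekends); an outreach reporting factor of 0.4; a 0.3 supervised
fraction; and the 151-day December-to-April window.

Children per antigen are Poisson (means 5–8 per session — small-session
counts typical of facility-level RI); doses opened are whole opened vials,
`ceil(c / vial_size) × vial_size`, with standard presentations (BCG and
OPV 20-dose, measles, yellow fever and IPV 10-dose, Penta single-dose) and
a 5% extra-vial rate as wastage noise. Clean sessions therefore always
satisfy `d ≥ c`, so impossible-count detection has a zero false-positive
rate on clean data by construction — the recovery tests assert precision
exactly 1.0, not approximately.

Error injection is parameterised per corruption: `impossible_count` (sets
`c = d + 1…5` for one antigen), `malformed_token` (damages one token so it
no longer parses), `missing_report` (extra drop of scheduled sessions) and
`zero_dose_outreach`. Every corruption is labelled in the retained ground
truth, keyed by message id, so precision/recall and rate biases are exact
bookkeeping, not estimates.

What the simulator does *not* emulate: telecom transport effects
(multi-part SMS, delivery delay, out-of-order arrival beyond timestamp
order), seasonal or campaign-driven demand, population denominators, or
facility-specific reporting styles. Passing recovery tests therefore show
the pipeline's bookkeeping is correct under the generator's assumptions,
not that real streams are this well behaved.

## The pilot fixture

`pilot_fixture()` reconstructs the pilot's published frame: 55 facilities
selected (25 urban-district, 30 rural-district), 50 included (24 + 26),
schedules configured so active-fleet expectations total exactly 66
fixed-post and 33 outreach sessions per week (hospitals plan 5/4/4, urban
PHCs 2, primaries 1; 33 of the 50 active facilities plan outreach — the
printed totals cannot be derived from the type mix alone, so they are
registry configuration), a 151-day window, and a 145-person training
cohort (8 state officers + 11 district officers + 20 ward focal persons +
106 facility staff) in its metadata.

A clean seeded base stream is overlaid with deterministic injections that
pin the published anomaly counts: 3 included facilities never report (47
of 55 participate); 24 reporting facilities get one fixed-post session
with a measles impossible count, 18 of them jointly impossible for BCG;
2 facilities get an outreach measles impossibility; 17 report zero measles
doses on an outreach session; 15 show BCG wastage of 0.85 and 2 sessions
show measles wastage of 0.90. Injections land on weekdays with no existing
message for that facility and session type, so the supersede rule never
consumes them. Base sessions in the fixture are clamped to wastage ≤ 0.80
and outreach children ≥ 1 so the pinned counts are exact rather than
approximate under the random base. The headline percentages (85, 91, 51,
36) are consequently invariant to the fixture seed, while message-level
content varies with it.

## Numerical and degenerate-input choices

* Percentages: nearest-integer rounding for display; underlying fractions
  retained in the objects.
* Ratios (sessions-vs-planned, wastage, supervision) are always recomputed
  from aggregated numerators/denominators at every roll-up granularity,
  never averaged across facilities.
* Supervision coverage with zero conducted sessions is returned as
  not-evaluable (`None`), not zero; supervised > conducted facility-days
  are flagged as violations but still counted.
* Empty inputs yield empty outputs (empty registry is an error only where
  a participation denominator is required).
* Completeness above 1 (over-reporting) is preserved, not clipped.

## Problem sizes

The default test run uses fleets of 8–75 facilities over 8-week to 151-day
windows (the recovery tests use 75 facilities over the full window to put
over 1,000 reported sessions behind the 3σ binomial check); the whole
suite completes in well under a minute, and `scripts/acceptance.py` in a
few seconds.

## Known limitations

* The full pilot code table was never published; the default table is an
  explicit assumption isolated in configuration.
* Reconciliation of corrected/re-sent SMS on the original servers is
  unknown; the supersede rule is this package's choice.
* Fleet-level reporting *curves* (weekly completeness trajectories) are
  emulated structurally, not calibrated to the pilot's unpublished
  per-facility reporting distribution.
* The dashboard export mimics an aggregate data-value layout; it does not
  speak any server API.
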