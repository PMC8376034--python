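# smsri

A self-contained toolkit for **daily SMS-coded routine-immunization (RI)
reporting**, modelled on the reporting platform piloted in Nasarawa state,
Nigeria. Health facilities (HFs) text a short coded summary at the end of
each vaccination session — how many children received each antigen and how
many vaccine doses were made available by opening vials — and a server
chain turns those texts into structured data and district dashboard
indicators. This package re-implements that whole chain as a library plus
CLI, with a synthetic facility-fleet simulator so the system runs and is
validated without any telecom or server infrastructure.

It is intended for health-information-system engineers and immunization
data analysts who want to prototype, stress-test, or teach SMS-based
administrative reporting and its data-quality checks.

## The message grammar and the quality model

Three message types travel over SMS:

* `WK` — planned sessions for the week (2 fields: fixed-post, outreach);
* `FS` — a conducted **fixed-post** session (15 fields);
* `OS` — a conducted **outreach** session (15 fields).

Each field is a letter+number token; in the default code table `a` is
children vaccinated with BCG and `f` is children vaccinated with measles
vaccine, so "15 children got BCG, 30 got measles vaccine" is texted as
`FS a15 f30`. Decoding is total: malformed tokens become issues, never
crashes, and missing letters decode as *absent*, not zero.

For each antigen in a session, with `c` children vaccinated and `d` doses
opened (whole vials), the open-vial wastage rate is

```
w = (d − c) / d,   w ≤ 1 always
```

and exactly one consistency state holds per antigen:

* **IMPOSSIBLE_COUNT** — `c > d` (more children vaccinated than doses
  available: a data-entry error, `w < 0`);
* **HIGH_WASTAGE** — `w > 0.80` (configurable threshold);
* consistent — `0 ≤ w ≤ 0.80`;
* not evaluable — either value absent, or `d = 0` without excess children.

On top of these the quality engine computes participation (distinct
reporting facilities / facilities selected), per-facility completeness
(reports received / reports expected from the planned weekly schedule),
weekly received-vs-expected session counts, weekday reporting profiles,
facility-level discrepancy summaries with explicit denominators, and
supervision coverage (sessions supervised / sessions conducted).

## Worked example

The packaged pilot-emulating fixture — 55 facilities selected across two
districts (25 urban, 30 rural), 50 included, a 151-day reporting window,
and fleet expectations of 66 fixed-post and 33 outreach sessions per
week — runs end-to-end with:

```bash
smsri pilot-demo --out demo/
```

which prints:

```
participation: 47/55 = 85%
included: 50/55 facilities
fixed-post measles discrepancy: 24/47 = 51%
joint BCG+measles discrepancy: 18/50 = 36%
supervision coverage: 0.30
```

Reading: 47 of the 55 selected facilities ever texted a report (85%
participation); during fixed-post sessions, 24 of those 47 reported more
children vaccinated with measles vaccine than doses opened at least once
(an impossible count, 51%); 18 of the 50 included facilities showed that
impossibility for *both* BCG and measles (36%); and roughly one conducted
session in three received a supervisory visit. The output directory holds
the registry, the raw coded message log, interpreted session reports, the
reject log, quality flags, and the dashboard export (`indicators.csv` in a
`dataElement,orgUnit,period,value` aggregate layout plus `dashboard.json`).

The same pipeline is available as library calls:

```python
from smsri import pilot_fixture, run_pipeline, participation

fx = pilot_fixture()
result = run_pipeline(fx.messages, fx.registry, fx.code_table)
summary = participation(result.session_reports, fx.registry, fx.window)
print(summary.n_reporting, summary.participation_percent)   # 47 85
```

Other CLI subcommands: `smsri simulate` (synthetic fleet with configurable
error injection), `smsri ingest` (raw log + registry → session reports and
rejects), `smsri check` (flags + discrepancy summary), `smsri report`
(dashboard export).

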