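# phitkit

A headless, scriptable engine for XML-defined mobile-health (mHealth)
study protocols. Researchers building self-help intervention studies
describe their apps almost entirely in XML: data-collection
*instruments* (screeners such as the PSQI, PCL-M, or PHQ-8 built from
forms of radio/checkbox/date/Likert *entities*), embedded skip and
validation logic in a small scripting language, an *intelligent virtual
advisor* (iVA) — an expert-system layer that stratifies risk from
screener scores and schedules tailored interventions — a task scheduler
extending the RFC5545 (iCalendar) VEVENT recurrence model, and a local
store of study-tagged records. phitkit interprets that whole stack on a
workstation, with scripted respondents standing in for the touch
screen, so protocols can be authored, executed, and regression-tested
without a mobile device.

## What it implements

- **Instrument model** — parse/validate the XML dialect (forms,
  entities, codebook items, vertical/horizontal layout, logic blocks on
  six lifecycle events), with round-trip serialization.
- **Logic language** — tokenizer, recursive-descent parser, and
  evaluator for the statement set `set / var / call / if…then /
  begin…end / while / goto / nextForm / exit`. Values are strings with
  read-only numeric coercion: `if ("{ptHx_age}" <= "2")` compares
  numerically when both sides parse as numbers, textually otherwise.
  `+` adds numbers or concatenates text; `-` subtracts numbers or two
  ISO dates (days). A registry of built-in API functions
  (`message`, `formatNumber`, `calculateAgeInMonths`, `scheduleTask`,
  `hide`/`show`, `findLatest`, `findLatestN`, `findByDate`,
  `findByPlacement`, …) is extensible with native functions.
- **Runtime** — headless sessions: per-form event order
  (`onFormEnter` → value changes → `onValidate` → `onFormExit`) wrapped
  in `onInstrumentEnter`/`onInstrumentExit`, required-field blocking,
  corrective `goto` re-entry, and background "script" instruments.
- **Advisor** — per-domain assess/plan programs over the global
  variable store, plus data-driven risk-alert rules (strictly-greater
  thresholds: PCL-M > 50, PSQI > 22, AUDIT > 20, GAD-7 > 15,
  PHQ-8 > 10).
- **Scheduler** — DTSTART/DTEND/DURATION/RRULE subset
  (FREQ ∈ {DAILY, WEEKLY, MONTHLY}, INTERVAL, BYDAY) plus the
  `P<n>DTA<h>H` offset-anchor start grammar; ordered, time-filtered
  visible task lists with `hide`/`show`.
- **Datastore** — SQLite-backed records tagged with project, study,
  protocol, case, observation ids and a timestamp; per-variable
  1-based *placement* ordinals; CSV export routed by
  development/test/production environment labels.
- **App configuration** — studies → protocols → {instruments, advisor,
  interventions}, eager cross-reference validation, and `a%b` task-id
  resolution.

## Worked example

Run the bundled sleep-assessment advisor against a completed screener
with a global score of 17:

```python
from datetime import datetime
from phitkit import EngineContext, Scheduler, TaskEntry, parse_advisor, run_advisor
from phitkit.fixtures import SLEEP_ADVISOR_XML

scheduler = Scheduler()
for t in ("sleep%environment", "mindfulness%bodyScan", "PSQI"):
    scheduler.add_task(TaskEntry(task_id=t))
ctx = EngineContext(now=datetime(2024, 3, 10, 14, 0), scheduler=scheduler)
ctx.store.set("PSQI_complete", "true")
ctx.store.set("PSQI_score", "17")
outcome = run_advisor(parse_advisor(SLEEP_ADVISOR_XML), ctx)
print(ctx.store.get("iVA_sleepRisk"), outcome.tasks_scheduled)
```

prints

```
3 ['sleep%environment', 'mindfulness%bodyScan', 'PSQI']
```

— a score of 17 falls in the third risk band (16–19), so the advisor
turns intervention on and schedules the two sleep/mindfulness tasks
plus a PSQI reassessment starting tomorrow at 08:00, every 3rd day.

The same flow end to end from a shell, using the bundled demo study
(17-item PCL-style and 19-item PSQI-style fixtures — structural
stand-ins, not the copyrighted instruments):

```sh
python - <<'EOF'
from phitkit.fixtures import write_fixture_app
write_fixture_app("demo")
EOF
phit gen-answers --instrument demo/psqi.xml --seed 7 --fixed 3 --out answers.txt
phit run --config demo/app.xml --study S1 --protocol A --case C1 \
     --instrument PSQI --answers answers.txt --db data.db \
     --now 2024-03-10T14:00:00
phit advise --config demo/app.xml --study S1 --protocol A --db data.db \
     --now 2024-03-10T14:00:00
```

The run transcript ends with `SET PSQI_score 21`, `SET PSQI_complete
true`, `RECORDS 21` (19 item records plus the saved score and
completion flag); the advise step then prints `SET iVA_sleepRisk 4`
(21 ≥ 20 is the top band) and the three `SCHEDULED …` lines.

## Scope

Headless by design: no rendering, skins, audio/image playback,
Bluetooth sensor acquisition, HTTPS upload, or dashboard — media
entities record a "presented" event and data leave the engine as CSV.
See `docs/methods.md` for the interpreter's semantics, the design
decisions taken where the dialect is underspecified, and known
limitations.
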