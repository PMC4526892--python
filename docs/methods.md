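# Methods

This note documents the semantics phitkit implements, the decisions
taken where the XML/scripting dialect is underspecified, and what the
bundled fixtures do and do not exercise.

## The instrument model

An instrument is an ordered list of forms; a form is a layout tree
(vertical/horizontal containers, static text, entity references) whose
`entityRef` leaves, in document order, define data-entry order. Two
printed layout dialects exist — entities directly under `<form>`, and
entities nested in containers — and the parser accepts both,
normalizing to a tree with an implicit vertical root. Entity types:
`radio`, `checkbox`, `text`, `likert`, `date`, `audioPlayback`,
`imageDisplay`, `chart`, `reactionTime`. Choice entities need at least
one `<item code=…>`; codes are the stored machine values, labels the
display text, and both are persisted. `required` defaults to false;
`save` on entities defaults to true (answers are recorded unless
opted out) and on static text to false. `styleName` attributes are
parsed and retained but have no behaviour in a headless engine.
Element and attribute names are matched case-sensitively.

Exactly six lifecycle events exist: `onInstrumentEnter`,
`onInstrumentExit`, `onFormEnter`, `onFormExit`, `onValueChanged`,
`onValidate`. Script (background) instruments have no forms and only
the two instrument-level events. `onFormEnter` has no printed usage
but is implemented for symmetry with `onFormExit`; it runs before the
respondent is consulted.

## The logic language

Statements end with `;` (including `begin;` and `end;`); `//` comments
run to end of line. Typographic quotes are normalized to ASCII before
lexing, and whitespace inside `{variable}` braces is trimmed — both
tolerances motivated by scripts pasted from word processors (one
printed script contains `{iVA_sleepRisk }`).

Values are strings. Coercion is read-only: a comparison evaluates
numerically iff *both* sides parse as decimal numbers, else as ordinal
text; `+` adds numbers or concatenates; `-` subtracts numbers, or two
ISO-8601 dates giving signed days (date-picker entities store ISO
dates). Booleans are the strings `true`/`false`; only `"true"` is
truthy. `&&`/`||` short-circuit. Precedence, loosest to tightest:
`||`, `&&`, comparisons, `+`/`-`; parentheses override. Both quoted
(`"{x}"`, interpolating) and bare (`{x}`) variable references are
accepted, as are bare numeric literals. A string literal that is not a
lone variable reference interpolates any embedded `{name}`
occurrences at evaluation time.

Deliberate decisions where the dialect is silent:

- **Undefined variables** read as the empty string with a logged
  warning, never an error — printed validation logic relies on
  `"{userHx_userID}" == ""` as an ordinary emptiness test.
- **While guard**: 100,000 iterations, then a runtime error, so a
  mis-authored loop cannot hang a headless test run.
- **`call f(…)`** is accepted both as a statement/assignment right-hand
  side (the printed usage) and as an expression primary; the latter is
  a conservative superset that makes short-circuit behaviour observable
  with counting stubs.
- **Function lookup is case-insensitive** (`message` and `Message` both
  appear in print); registration rejects duplicates, so built-ins
  cannot be shadowed.
- **`generateCollectionId`** returns a session-monotonic integer
  starting at 0 and is injectable for tests.
- **`calculateAgeInMonths`** counts completed months to the engine
  clock; any future date returns a negative value (at least −1), since
  authored validation detects future birthdays via `< "0"`.
- **`formatNumber`** renders with exactly N fractional digits,
  half-up.
- **Multi-valued query results** (`findLatestN`, `findByDate`,
  `findByPlacement`) reach scripts joined with `|`, the same separator
  checkbox multi-selects use.

## Sessions

Event order per interactive session:
`onInstrumentEnter`, then per form `onFormEnter` → per answered entity
a store write (`instrument_entity = code`) and `onValueChanged` on the
entity then the form → `onValidate` on each entity then the form →
`onFormExit` → advance; finally `onInstrumentExit`. `goto` repositions
the form cursor (validating logic uses it to re-enter a form with a
corrective message); `nextForm` advances; `exit` jumps to the
instrument-exit logic. A form-visit budget (1,000) turns authored
navigation loops into errors.

A missing required answer blocks navigation: the session stops,
marked incomplete, with the violation recorded, and — our decision —
without running `onInstrumentExit`, mirroring a user quitting
mid-instrument. Codebook violations (an answer outside a
radio/checkbox item set) are recorded but defer to author logic; the
offending value is never stored. "Skip" answers leave the variable
unset, distinguishing not-asked from answered-blank. Checkbox
multi-selects store their codes joined by `|` in the single
`instrument_entity` variable.

Answers arrive from a provider; the scripted provider reads
`form.entity=code` lines, consumed in order per entity so a re-entered
form can receive a corrected answer from a later line.

## Advisor

Assess blocks run in document order against the shared store; all
effects (variable writes, schedule requests, alerts, messages) are
captured per run. Reassessment cadence is not advisor state — it is
whatever schedule the study gives the advisor task. The printed sleep
script stratifies PSQI scores into bands 0–7 / 8–15 / 16–19 / ≥20
(risks 1–4) and fires its plan at risk ≥ 3, i.e. score ≥ 16; the
narrative description "exceeds 16" differs by one at the boundary, and
the engine follows the code. Risk alerts are data (`<alert>` elements:
domain, score variable, strictly-greater threshold, message), so
studies can override thresholds without code changes; alerts surface
as logged messages, not UI.

## Scheduler

Supported rule surface: DTSTART, DTEND, DURATION, RRULE with
FREQ ∈ {DAILY, WEEKLY, MONTHLY}, INTERVAL ≥ 1, BYDAY. Both the
standard semicolon RRULE dialect and the comma dialect printed in
advisor scripts are accepted (commas normalized to semicolons). The
offset-anchor start grammar `P<n>D[TA<h>H]` — *n* days from now,
optionally anchored to *h*:00 local — is **reverse-engineered**: the
extension is used in print (`"P1DTA8H"` beside the prose "every 3rd
day at 8 am") but never defined, so this grammar is a documented
reconstruction. All datetimes are timezone-naive local times
(single-device semantics). An occurrence's default visibility window
runs to the end of its calendar day; an explicit DURATION overrides
that. Re-scheduling a task replaces its rule; past occurrences of a
replaced rule are not retained. `hide` is idempotent and the last
hide/show command wins. Weekly expansion counts Monday-started weeks
from the start's week; monthly expansion keeps the start's day-of-month
and skips months lacking it — behaviour verified in tests against an
established RFC5545 recurrence library on the shared subset.

## Datastore

Records carry all six tags (project, study, protocol, case,
observation, timestamp). *Placement* is per-variable and 1-based, with
inclusive ranges ("between the fourth and eighth save" reads
naturally as inclusive); whether placement should instead be global
across variables is genuinely ambiguous, and the per-variable choice
is flagged here. The observation id increments once per instrument
session so all of a session's records group together for
re-administration analysis. Backend: single-file SQLite ( `:memory:`
for tests); read-only stores model lookup tables and reject writes.
Encryption at rest is a pluggable codec hook — identity by default,
and any non-identity codec makes opening require a password; no
specific cipher is mandated. CSV export writes the fixed header
`project_id,study_id,protocol_id,case_id,observation_id,timestamp,instrument,entity,code,value`;
the development/test/production environment label routes the output
directory only, keeping test data out of the production tree.

## Fixtures and the synthetic respondent

The bundled full-length screeners are structural stand-ins: the
17-item PCL-style fixture (five-point scale, per-form counting of
answers ≥ 3) and the 19-item PSQI-style fixture (global score as the
sum of seven 0–3 component stand-ins, range 0–21) reproduce item
counts, variable names, codebooks, and score ranges but not the
copyrighted item text. The single-form PCL excerpt, the multi-entity
family form, the patient-history snippets, and the sleep advisor
reproduce the published worked examples. The demo app binds them into
one study with two protocols: A (instruments + advisor +
interventions) and B (data collection only).

The synthetic respondent is seeded and deterministic: uniform draws
over each choice entity's codebook, or a fixed-profile code for every
entity; by default it answers exactly the required entities. It
emulates answer *selection* only — no response latencies, missingness
patterns, or item correlations — so passing tests demonstrate the
engine's contract (parsing, event order, logic semantics, persistence),
not psychometric realism of simulated participants.

## Problem sizes in the test and acceptance runs

Desk-scale throughout, chosen to keep the whole suite comfortably
under a minute: 200 seeded sessions for the event-order invariant,
500 seeds for the binomial answer-distribution check, 1,000 random
save sequences for datastore consistency, 1,000 hypothesis cases for
numeric-coercion agreement with arbitrary-precision decimals, 90–180
day windows for recurrence equivalence.

## Known limitations

- No rendering, media playback, sensors, upload transport, or
  dashboards (headless scope); media entities only record presentation.
- Arithmetic is `+`/`-` only; no user-defined script functions
  (extension is via the native-function registry).
- The six named lifecycle events are the complete event surface.
- Intervention content is structural (slide-show skeletons), not
  clinical material.
- The scheduler keeps only each task's active rule; historical rules
  are not queryable.
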