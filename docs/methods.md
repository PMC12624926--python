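# Methods

## The problem

Intravenous drug self-administration studies in rats generate one
letter-coded MedPC text file per controlling computer per session (up to 16
operant chambers per computer; a 60-rat cohort therefore produces 4 raw
files per session). Animals press an *active* lever for a drug infusion
under FR1 with a 20-second post-infusion timeout (presses during the
timeout are recorded but not reinforced); an *inactive* lever has no
consequence. Alongside the operant files, the lab maintains standardized
spreadsheets: Cohort Information (one row per animal, RFID as the unique
key), Daily Issues (session-level observations with a keep/discard
decision), Exit (animals leaving the study with their *last good session*),
three non-operant assays (Von Frey nociception, tail-immersion analgesia,
bottle-brush irritability), and a Corrections Record listing session
workbooks that must be reprocessed after manual fixes.

`operantdb` turns these inputs into a relational store and a curated,
versioned release, entirely on a local filesystem with an embedded SQLite
database — no cloud services, no scheduler of its own (cron or Task
Scheduler invoke the CLI).

## Parsing model

**MedPC dialect.** Each box block starts at a `Start Date:` header line and
carries `End Date`, `Subject`, `Box`, `Start Time`, `End Time`, `MSN`,
followed by scalar lines (`F:   82.000`) and array blocks (`Y:` with
indented index-prefixed rows of up to five values). Letter→meaning
assignments are program-specific, so they are a configurable `VariableMap`;
the default encodes the conventional assignments (B = active lever-press
count, W = infusions per 5-min bin, Y = active-press timestamps) plus this
package's canonical choices for the remaining roles. Timestamps are real
seconds from session start; `timestamp_unit` converts centisecond-tick
dialects.

**Zero padding.** MedPC arrays are fixed-size and zero-padded. Trailing 0.0
values are stripped; the count scalars are the source of truth for array
length, and an all-zero array with count 1 is read as a single event at
t = 0. Event times are handled on a centisecond grid end to end, so
write→parse round trips are bit-exact.

**Filename grammar.**
`<LOCATION><COMPUTER>_<COHORT>_<DRUG>_<SESSIONID>.txt`, e.g.
`MTF134A_C01_OXY_LGA10.txt`, with COMPUTER ∈ A–E, COHORT = C + 2 digits,
DRUG ∈ {OXY, COC}, SESSIONID = (SHA|LGA|PR|SHOCK) + 2-digit index (> 99
rejected). Parse failures name the offending grammar element and feed the
gap diagnostics rather than dying silently.

## Store and exclusion semantics

One operant table per session type plus subject, measurement, issue, exit,
and behavioral-test tables, all keyed on RFID. Ingest is idempotent and
keyed by source filename: re-ingesting a corrected workbook replaces its
rows. Operant rows whose subject ID has no RFID in their cohort are
quarantined with a logged referential warning, never dropped silently.

The combined table is the inner join of operant rows with subject fields,
minus (a) rows matched by a discard-decision issue — by (RFID, session ID)
when the issue names a session, else by (RFID, date) — and (b) rows
ordered after the animal's last good session. Session order uses the
recorded session date when available and the token order
(SHA → LGA → PR → SHOCK, then index) as fallback; dates are ground truth.
An exit row without a last good session excludes all sessions strictly
after the exit date (the paper-trail-conservative reading). Keep-decision
issues annotate their rows instead of removing them. Saline/sham/naive
animals get no special casing.

## Curation rules

Applied strictly in the order outliers → imputation → derived variables,
per rat, per variable, per phase, over the cohort-wide session axis of the
phase (so a rat's absent sessions appear as gaps):

* **Outliers** (cap = 250, strict `>`): exactly one over-cap session in a
  rat's per-phase infusion series ⇒ remove that session's infusions *and*
  active presses (both become ordinary missing cells, eligible for
  imputation); ≥ 2 over-cap sessions ⇒ the rat is a genuine high presser,
  every exceeding infusion value is capped at 250 and actives are left
  untouched. "Multiple outliers" is read per rat per phase.
* **Imputation**: isolated interior gap → mean of the two neighbors
  (`imputed_linear`); single edge gap → mean of the two nearest observed
  values on the one observed side (`imputed_nn`; one value is used if only
  one exists); runs of ≥ 2 missing sessions, interior *or* at the edge, are
  never imputed (the multi-gap rule wins the tie at edges). Series with
  fewer than two observed values are returned unchanged with a warning.
  The operation is idempotent. Infusions, active, and inactive presses are
  imputed identically.
* **Derived variables** (formulas configurable; defaults follow the
  composite-addiction-score literature): escalation index = least-squares
  slope of LgA infusions against 1-based session number, missing sessions
  keeping their session numbers; intake total = sum of curated infusion
  values over all phases; motivation = mean PR breakpoint; shock
  resistance = mean infusions-after-shock divided by mean curated LgA
  intake; z-scores use the sample standard deviation (ddof = 1) over the
  standardization population (default: all non-excluded drug-group animals
  in the database); AI = mean of the three z-scores, absent if any
  component is absent (absences are logged, never filled). A rat missing a
  whole phase simply lacks that component.

A stable release is written once per version tag — a second write with the
same tag is refused — together with a JSON sidecar recording cap,
imputation config, and a hash of the AI formula.

## Synthetic cohorts

The generator's defaults are the study conditions: 60 rats,
16-chamber computers (4 raw files per session), 2-h ShA × 4, 6-h LgA × 14,
PR × 2, shock × 2, one session per day, FR1 with a 20-s timeout. The
behavior model is a renewal process: presses arrive with exponential
waiting times whose mean is set so that mean inter-infusion interval
(timeout + wait) matches the target rate — 8 infusions/h at baseline, with
a per-rat LgA escalation slope drawn from N(2.5, 1.0) infusions/session.
Presses inside a timeout window are timeout presses (plus a Poisson(1)
burst per window); inactive presses are an independent 4/h Poisson
process. PR breakpoints come from a per-rat motivation trait
(N(12, 4), ≥ 1); shock-session intake from a per-rat compulsivity fraction
(U(0.2, 0.9)). Where the defaults are not dictated by the paradigm itself
(session counts, rates, trait distributions) they are one-time choices in
the range of published cocaine/oxycodone self-administration cohorts.

Anomalies are injected after simulation by overwriting counts and arrays
(over-cap sessions get physically consistent ≥ 20-s-spaced event trains),
so ground truth stays exact: by default one single-outlier rat, one
three-outlier rat, three missing raw-file blocks, one discard issue, two
keep issues, and two mid-LgA exits whose later sessions remain in the raw
files and must be excluded at combine time. All randomness flows from one
seed through named substreams (behavior / anomalies / metadata); the same
seed yields a byte-identical directory tree.

A `noise="none"` mode produces exactly linear LgA series (integer slopes),
evenly spaced events, and deterministic counts, so parameter recovery can
be asserted exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: within-session satiation or pharmacokinetics,
circadian structure, correlated traits across animals, messy hand-entered
spreadsheet formatting beyond header-case variation, and hardware artifacts
other than the modeled anomaly classes. It is a contract fixture, not a
calibrated addiction simulator.

An independent oracle (`synth_fixtures.oracle_curate`) re-derives the
expected stable table from ground truth with straight-line loops, sharing
no code with the curation module; the test suite requires the full
parse → store → combine → curate pipeline to match it cell-for-cell, flags
included.

## Reporting conventions

Report data (tidy CSV/JSON) is the tested contract; PDF/XLSX rendering is
best-effort on top of the same numbers. Group traces use SEM
(sd(ddof = 1)/√n; 0 when n = 1), computed per session over non-excluded
animals only; imputed values participate by default (configurable).
Missing sessions are rendered as gaps, never interpolated for display.
Inter-infusion intervals are successive differences of the infusion
timestamps (≤ 1 timestamp ⇒ empty set); the histogram bin width defaults
to 60 s. The behavior matrix copies stored values — no recomputation — with
blank cells exactly where no record exists.

## Problem sizes

The test suite and acceptance script run on scaled-down cohorts chosen as
the smallest sizes that exercise every rule: 8 rats × 11 sessions for the
pipeline/oracle fixtures, 60 rats × 1–2 sessions for the capacity checks,
100 seeded simulations for the stochastic slope-recovery and timeout
properties. The curation, store, and parsing code paths are identical at
full scale; only the simulated cohort is smaller.

## Known limitations

* One writer at a time (SQLite, no service layer or authentication).
* The exact dependent-variable list of any particular lab is configurable
  but not auto-discovered; defaults are the three-component composite.
* Sessions spanning midnight rely on the date fields being correct;
  duration is inferred modulo 24 h when end time precedes start time.
* The interactive timeline is delivered as its JSON data contract plus
  static renders; no hosted dashboard is included.
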