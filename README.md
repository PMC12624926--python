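# operantdb

A local, self-contained data pipeline for operant drug self-administration
studies. It takes the raw output of MedPC-controlled operant chambers (one
letter-coded TXT file per computer per session, up to 16 box blocks each),
integrates it with standardized cohort / daily-issue / exit / behavioral-test
spreadsheets in an embedded relational store keyed on each animal's RFID,
applies the lab's curation rules, and produces the daily summary and
visualization artifacts a large self-administration operation runs on.

It is written for behavioral-neuroscience labs running multi-cohort
oxycodone or cocaine self-administration paradigms (short-access ShA,
long-access LgA, progressive-ratio PR, and foot-shock sessions) at a scale —
dozens of rats, dozens of sessions, several computers — where hand-curated
spreadsheets stop being tenable.

## What it computes

Three database tiers, mirroring daily lab practice:

* **raw** — everything parsed from files, preserved verbatim; one row per
  rat-session, tables joined on RFID;
* **combined** — raw ⋈ subject metadata, minus sessions discarded in the
  Daily Issues file and sessions after an exited animal's *last good
  session*;
* **stable** — a versioned, immutable curated release.

Curation applies three rules in order, per animal, per variable, per phase:

1. **Syringe-capacity outliers.** A session with infusions > 250 is
   physically impossible (the syringe holds 250). One such session in a
   series ⇒ its infusion *and* active-lever values are removed; two or more
   ⇒ a genuinely high-pressing animal, so exceeding infusion values are
   capped at 250 (actives untouched). ≤ 250 is never modified.
2. **Imputation.** A single-session gap is filled with the mean of its two
   neighbors; a single gap at the series edge with the mean of the two
   nearest observed values on its one observed side; runs of ≥ 2 missing
   sessions are left missing. Every cell carries a provenance flag
   (`observed`, `removed_outlier`, `capped`, `imputed_linear`, `imputed_nn`,
   `missing`).
3. **Derived phenotypes.** Per animal: the escalation index (least-squares
   slope of LgA infusions vs. session number), mean PR breakpoint
   (motivation), shock resistance (mean infusions under shock relative to
   baseline LgA intake), their population z-scores, and the composite
   Addiction Index

   AI = ( z(escalation) + z(breakpoint) + z(shock resistance) ) / 3,

   present only for animals with all three components.

Reports include the per-animal behavior-trace report (each animal against
cohort, male, and female means ± SEM), the cohort behavior matrix
(animals × sessions per variable, with issue and exit annotations), event
rasters and inter-infusion-interval histograms from the timestamp arrays,
and gap diagnostics that surface naming mistakes and missing files as
visible data gaps.

A fully seeded synthetic-cohort generator (`operantdb.synth_fixtures`)
emulates every input — renewal-process FR1 pressing with the 20-s
post-infusion timeout, linear LgA escalation, injected >250 outliers,
missing sessions, issues, and exits — with machine-readable ground truth
and an independent brute-force curation oracle, so the entire pipeline is
testable without animal data.

## Worked example

Generate a 16-rat synthetic cohort and run the full pipeline:

```
$ operantdb simulate --seed 42 --n-subjects 16 --out .
synthetic cohort written to .
$ operantdb convert
converted 22 file(s); 0 failure(s)
$ operantdb ingest
ingested 349 operant row(s)
$ operantdb combine
combined table: 328 row(s) (21 excluded)
$ operantdb curate --release v1
stable release v1 written to output
$ operantdb report --kind gaps
3 gap record(s)
```

The 22 sessions (4 ShA, 14 LgA, 2 PR, 2 shock) of 16 rats give 352
rat-sessions; 3 are missing raw-file blocks (hence 349 ingested and the 3
gap records), 1 is discarded through a daily issue and 20 fall after two
exited animals' last good session (hence 328 combined rows, 21 excluded —
each exclusion is logged with its reason and appended to
`output/events.jsonl`). The stable release lands in
`output/stable_v1.csv` with one flagged value per rat × session × variable:

```
rfid,phase,session,variable,value,flag
933000320100001,LGA,LGA01,active,42.0,observed
933000320100001,LGA,LGA02,active,43.0,observed
...
```

and `output/phenotypes_v1.csv` holds the per-animal derived variables:

```
rfid,escalation_index,intake_total,pr_breakpoint_summary,shock_resistance,...,addiction_index
933000320100001,0.9164835164835172,824.0,18.0,0.01969057665260197,...,-0.47235295624437507
```

Rat `…001` gained ≈ 0.92 infusions per LgA session, took 824 infusions in
total, reached a mean PR breakpoint of 18, and sits below the cohort mean on
the composite Addiction Index (−0.47). The two exited animals have no AI
(their PR/shock phases fall after their last good session) — absences are
reported, never silently filled.

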