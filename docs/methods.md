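# Methods

## Data model and ingestion

The unit of analysis is the deduplicated safety report (case). FAERS-style
quarterly extracts arrive as six "$"-delimited tables; parsing is lossless
and lenient: every non-header line yields a record, blank or malformed
dates become an explicit *missing* precision rather than an error, and
partial dates (YYYYMM, YYYY) are retained with their precision so that
downstream stages — not the parser — decide usability.

Deduplication follows the receipt-date convention for spontaneous-report
versions: within a CASEID, keep the row with the latest FDA_DT, breaking
ties by the numerically larger PRIMARYID. Since PRIMARYID is the
documented successor of the retired ISR key, the tie-break is implemented
on it; the operation is idempotent and leaves exactly one row per case.

Product attribution uses only primary-suspect (PS) drug rows. Name
matching is exact on normalized strings (upper-cased, trimmed, internal
whitespace collapsed) against a per-product synonym list; no fuzzy
matching, so attribution is deterministic and auditable. A case whose PS
rows match several products is attributed to each. Age is normalized to
years from AGE/AGE_COD (DEC×10, YR×1, MON÷12, WK÷52, DY÷365, HR÷8760);
results outside [0, 120] become missing. A case is *serious* iff it
carries at least one outcome code in {DE, LT, HO, DS, CA, RI}; OT alone is
non-serious.

## Event normalization

MedDRA is licensed, so the dictionary is an input: a TSV mapping verbatim
PT → (current PT, SOC), looked up case-insensitively. Unmapped terms are
flagged and counted, never dropped. Composite event groups (Tremor,
Facial paralysis, Cytokine release syndrome, HLH, Graft versus host
disease, Respiratory failure, Pleural effusion, Tachycardia, Hypotension,
Shock) ship as an editable YAML transcription of the published CAR-T
signal tables' footnotes; load-time validation enforces that a PT belongs
to at most one group, which makes grouping idempotent. Grouping uses set
semantics: a case reporting several members of one group contributes one
count for the group label. Infection PTs can additionally be classed as
bacterial/fungal/viral; because the pathogen-type hierarchy is licensed
MedDRA content, the shipped class lists are a small synthetic stand-in
covering the fixture vocabulary, intended to be replaced by HLGT
membership from a licensed dictionary.

## Disproportionality screen

Each (product, event) pair with a ≥ 1 is screened on the 2×2 table of
unique-case counts against the full ingested universe ("all other
reports"), the background the published CAR-T analysis screens against; a
`within-class` comparator restricting the background to the other listed
products is available for sensitivity analysis. Statistics:
ROR = ad/bc with the log-normal CI exp(ln ROR ± z·se),
se = √(1/a+1/b+1/c+1/d); PRR = [a/(a+b)]/[c/(c+d)]; Pearson χ² with
optional Yates correction. The z quantile is the exact normal quantile
(1.959964…), not 1.96. The signal rule is the MHRA-style joint criterion
N ≥ 3, CI-low > 1, PRR > 2, χ² > 4 — N non-strict, the rest strict — and
output is ordered by descending ROR within product, ties broken by event
label for determinism.

Numerical edge cases: a zero cell makes the ROR (and for c = 0 the PRR)
undefined; the default is a hard, named error per pair — reported in the
screen as a `zero-cell` status row, never silently corrected — with the
Haldane–Anscombe +0.5 correction available behind an explicit flag,
because silent corrections would distort the ROR ranking. χ² defaults to
the uncorrected formula, matching the classic MHRA/Evans criterion; both
choices are surfaced as flags. No multiple-testing adjustment is applied,
mirroring standard practice for this screen. Bayesian shrinkage methods
(BCPNN/IC, MGPS/EBGM) are out of scope.

## Descriptive layers

*Demographics*: per-product counts and percentages over sex, age windows
(<18, 18–64, ≥65, unspecified), reporter occupation (health professional /
consumer / not specified), reporting region via an editable country→region
lookup, first-listed indication, seriousness and outcome codes. Every
block except outcomes (which are multi-select) partitions the product's
case total, and percentages recompute exactly from counts before
rounding.

*Time to onset* is EVENT_DT − START_DT in whole days, anchored on the
earliest START_DT among the case's primary-suspect therapy rows (the
infusion date is the clinically meaningful anchor; earliest is
conservative). A pair is retained only when both dates have day precision
and the interval is non-negative; otherwise it is excluded as *missing*,
*partial* or *negative*, and retained + exclusions always telescope to the
candidate total. Partial dates are excluded rather than imputed by
default; `impute_mid` maps month→15th and year→July 1 for sensitivity
use. Onset windows use upper-inclusive edges (default 7, 30, 60), so
"within 7 days" means days ≤ 7.

*CRS overlap* for an event is the share of its cases that also report the
grouped cytokine-release-syndrome label (which covers cytokine storm),
over all cases carrying the event. *SOC distribution* reports, per
product, the share of positive signals in each system organ class; a
`pairs` denominator variant divides by all screened pairs instead.

## Synthetic universe

The generator emulates the six-table relational structure with known
ground truth. Associations are planted on the odds scale: for an event
with background report rate r (odds o = r/(1−r)) and a planted multiplier
m, cases on the product draw the event with probability m·o/(1+m·o), so
the true case-level odds ratio is exactly m and recovery tests have an
analytic target. Defaults describe a CAR-T-like screen: two products at
prevalences 5% and 3% of reports, a ten-event panel with background rates
0.5–5%, duplicate-version rate 5%, partial-date rate 10%, onset drawn
log-normal with median 5 days and σ = 1 (echoing the early post-infusion
peak of acute CAR-T toxicity), demographic margins loosely matching a
spontaneous-report cohort, and quarterly span 2017Q4–2024Q1. Duplicate
versions re-emit a case with a later FDA_DT and a higher PRIMARYID and
never alter clinical content, so deduplication correctness is decidable
from ground truth. A filler reaction ("drug ineffective") guarantees
every case reports at least one event without touching any screened
pair's cells. All randomness flows from one seeded generator; identical
configs give byte-identical files.

What the emulator does **not** model: name-variant noise beyond
case/whitespace, free-text narratives, dosage, event-dependent reporting
lags, correlated events within a case, or secular trends in reporting
volume. Passing recovery tests therefore demonstrates correctness of the
screening arithmetic and plumbing on FAERS-shaped data, not robustness to
the messiness of real FAERS name fields — real analyses must curate their
product synonym lists and dictionary.

## Problem sizes used in validation

Formula agreement is checked on 1,000 random positive tables against an
independently coded brute-force evaluation (tolerance 1e-9 relative). CI
calibration uses 2,000 multinomial tables of size 100,000 at a known odds
ratio of 2. Planted-signal recovery runs the full
generate→deduplicate→normalize→screen path at n = 100,000 cases for 100
seeds (multiplier 10, prevalence 5%, background 1%); the null
calibration pools 50 seeds of 20,000-case universes with nothing planted.
The hand-checked fixtures (12-case and 4-case universes) pin every
downstream number to arithmetic documented in `docs/fixtures.md`.

## Known limitations

- The comparator universe is whatever was ingested; screening a single
  product against a tiny background yields unstable RORs (wide CIs are
  reported, not suppressed).
- PT normalization is only as good as the supplied dictionary; the
  bundled TSV is a synthetic demonstration covering the fixture
  vocabulary.
- Multi-product cases contribute to every matching product's table, so
  product rows are not independent across products.
- Time-to-onset uses the single case-level EVENT_DT that the extract
  carries; it cannot distinguish onset per event within one case.
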