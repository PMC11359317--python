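# Hand calculations behind the canned fixtures

## `tiny-hand-checked` (12 cases)

Product cases (PS = TISAGENLECLEUCEL): 100–103. Background cases
(PS = IBUPROFEN): 104–111.

### DEMO versions and deduplication

| CASEID | versions (PRIMARYID @ FDA_DT) | kept | why |
|--------|-------------------------------|------|-----|
| 100 | 1001 @ 2023-01-01, 1003 @ 2023-03-01 | 1003 | latest FDA_DT |
| 101 | 1011 @ 2023-02-15, 1015 @ 2023-02-15 | 1015 | FDA_DT tie → higher PRIMARYID |
| 102–111 | single version 1021…1111 | that version | only one |

14 DEMO rows in, 12 cases out. Kept PRIMARYIDs:
1003, 1015, 1021, 1031, 1041, 1051, 1061, 1071, 1081, 1091, 1101, 1111.

### Reactions (after dictionary + grouping)

CYTOKINE STORM normalizes to "Cytokine storm" and groups into the
"Cytokine release syndrome" label.

| case | events |
|------|--------|
| 100 | CRS, Hypotension |
| 101 | CRS (via cytokine storm), Hypotension |
| 102 | Pyrexia, Hypotension |
| 103 | Headache, Hypotension |
| 104 | CRS, Hypotension |
| 105 | CRS (via cytokine storm), Hypotension |
| 106 | Headache, Hypotension |
| 107 | Pyrexia, Hypotension |
| 108, 109 | Fatigue |
| 110 | Headache |
| 111 | Pyrexia |

### 2×2 for (tisagenlecleucel, Cytokine release syndrome)

a = 2 (100, 101); b = 2 (102, 103); c = 2 (104, 105); d = 6 (106–111).

- ROR = (2·6)/(2·2) = **3.0**
- se = √(1/2 + 1/2 + 1/2 + 1/6) = √(5/3) = 1.29099;
  CI = exp(ln 3 ± 1.959964·1.29099) = (**0.2389**, **37.67**)
- PRR = (2/4)/(2/8) = **2.0**
- χ² = 12·(2·6 − 2·2)² / (4·8·4·8) = 12·64/1024 = **0.75**
- Signal verdict: **no** (N = 2 < 3; PRR not > 2; χ² not > 4)

For (tisagenlecleucel, Hypotension): a = 4, b = 0, c = 4, d = 4 — a
zero-cell pair; with the Haldane +0.5 correction
ROR = (4.5·4.5)/(0.5·4.5) = 9.0; PRR = (4/4)/(4/8) = 2.0;
χ² = 12·16²/(4·8·8·4) = 3.0.

### CRS overlap ("the 8-case overlap fixture")

Hypotension cases: 100–107 (8 cases). Of these, 100, 101, 104, 105 also
carry the CRS label → overlap rate = 4/8 = **0.5**.

### Time to onset (product cases only)

| case | START_DT | EVENT_DT | result |
|------|----------|----------|--------|
| 100 | 2023-01-01 | 2023-01-15 | retained, **14 days** |
| 101 | 2023-02-10 | 2023-02-10 | retained, **0 days** |
| 102 | 2023-01-01 | 2023-02 (month) | excluded(**partial**) |
| 103 | 2023-03-01 | 2023-02-15 | excluded(**negative**) |

Accounting: total 4 = retained 2 + partial 1 + negative 1.

### Demographics (product cases 100–103)

Ages 10, 30, 70, 45 → <18: 1, 18–64: 2, ≥65: 1. All four carry outcome
HO → 4 serious, 0 non-serious.

## `messy-dates` (4 cases)

One product case per onset branch:

| case | START_DT | EVENT_DT | branch |
|------|----------|----------|--------|
| 200 | 2023-01-01 | 2023-01-15 | retained (14 days) |
| 201 | 2023-01-01 | (blank) | missing |
| 202 | 2023-01-01 | 2023-01 | partial |
| 203 | 2023-02-01 | 2023-01-15 | negative |

Each exclusion reason fires exactly once and
total 4 = retained 1 + missing 1 + partial 1 + negative 1.

## `planted-signals` / `null-universe` (sampled, seed 1234)

Generated scenarios, 4,000 cases, two products (prevalence 6% and 5%).
`planted-signals` plants odds multipliers 25 on (product A, cytokine
release syndrome) and 20 on (product B, hypoxia); both pairs must meet the
joint criteria. `null-universe` plants nothing; the flagged fraction
stays below 5%. These two are checked statistically, not by hand.
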