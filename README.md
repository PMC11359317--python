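# pvsignal

Disproportionality signal detection for spontaneous adverse-event reports
in the FAERS quarterly-extract dialect, built for pharmacovigilance
analyses of the six FDA-approved CAR T-cell products (tisagenlecleucel,
axicabtagene ciloleucel, brexucabtagene autoleucel, lisocabtagene
maraleucel, idecabtagene vicleucel, ciltacabtagene autoleucel) — and for
any other drug/event screen over the same data model.

It is aimed at pharmacoepidemiologists and biostatisticians who want a
tested, scriptable replacement for the usual SAS/SPSS pipeline: ingestion
and deduplication of the quarterly DEMO/DRUG/REAC/THER/OUTC/INDI tables,
MedDRA-style preferred-term normalization with composite event groups,
reporting-odds-ratio screening under the MHRA joint criteria, and the
descriptive layers (cohort demographics, time to onset, cytokine-release-
syndrome overlap). A synthetic FAERS emulator with planted associations
makes the whole pipeline testable without downloading anything.

## The statistics

For a product *D* and event *E*, deduplicated case reports are collapsed
into the 2×2 table

|              | event *E* | other events |
|--------------|-----------|--------------|
| reports of *D*     | a | b |
| all other reports  | c | d |

and screened with

- **ROR** = (a·d)/(b·c), with the log-normal 95% CI
  exp(ln ROR ± z₀.₉₇₅·√(1/a + 1/b + 1/c + 1/d)),
- **PRR** = [a/(a+b)] / [c/(c+d)],
- **χ²** = n(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)], n = a+b+c+d
  (Yates' correction available behind a flag).

A (product, event) pair is a **signal** when jointly: N = a ≥ 3, the lower
95% CI bound of the ROR > 1, PRR > 2 and χ² > 4. Results are ordered by
descending ROR within product. Counting is per deduplicated case with set
semantics per event label, so a case reporting two members of one
composite group (e.g. "tremor" and "intention tremor" under **Tremor**)
counts once.

## Worked example

```python
from pvsignal import DisproportionalityModel, SynthConfig, generate
from pvsignal.faers_io import dedup_bundle, filter_primary_suspect
from pvsignal.meddra import TermDictionary, bundled_path, load_term_groups, normalize_reactions

cfg = SynthConfig(
    n_cases=100_000,
    products=(("CARPRODUCT A", 0.05),),
    planted=(("CARPRODUCT A", "CYTOKINE RELEASE SYNDROME", 10.0),),
    seed=7,
)
bundle, truth = generate(cfg)                      # six FAERS-style tables
clean = dedup_bundle(bundle)                       # one row per CASEID
cases = filter_primary_suspect(clean.drug, cfg.product_names)
dictionary = TermDictionary.from_tsv(bundled_path("synthetic_pt_dictionary.tsv"))
universe = normalize_reactions(clean.reac, dictionary, load_term_groups())

results = DisproportionalityModel(universe, cases).fit()
print(results.summary())
```

prints (abridged):

```
Disproportionality screen (ROR / PRR / chi-square, MHRA-style criteria)
universe: 100000 cases, 11 event labels; comparator: full
criteria: N>=3, ROR CI low>1.0, PRR>2.0, chi2>4.0 (alpha=0.05)
pairs screened: 11; signals: 1

     product                     event   n   ror  ci_low  ci_high  prr    chi2  is_signal
CARPRODUCT A Cytokine release syndrome 464 10.84    9.66    12.18 9.91 2493.58       True
CARPRODUCT A               Hypotension 163  1.17    1.00     1.38 1.17    3.74      False
CARPRODUCT A                   Hypoxia  45  1.12    0.83     1.52 1.12    0.57      False
...
```

The planted pair is recovered near its true odds multiplier of 10 (here
ROR = 10.84 with CI 9.66–12.18 at a = 464 cases) and is the only pair
meeting the joint criteria; every unplanted event sits near ROR 1.

The same run is available from the shell:

```sh
pv-signal synth --fixture planted-signals --out data/
pv-signal run --config run.yaml --seed 7
```

writing `signals.tsv`, `demographics.tsv`, `onset_bins.tsv`,
`overlap.tsv`, `soc_distribution.tsv` and a `manifest.json` whose
per-stage record counts telescope (versions in = cases + duplicates
removed; onset candidates = retained + missing + partial + negative).

Real FAERS quarterly extracts are screened the same way: point
`pv-signal ingest --quarters 2017Q4:2024Q1 --faers-dir <dir>` at the
"$"-delimited ASCII packets, supply your product synonym list and a
licensed PT→SOC dictionary TSV, and run the same screen/profile stages.

## Layout

- `src/pvsignal/quarters.py`, `dates.py` — quarter spans, partial-precision dates
- `src/pvsignal/faers_io.py` — "$"-delimited table parsing, PS filtering, deduplication
- `src/pvsignal/meddra.py` — PT dictionary interface, composite term groups, pathogen classes
- `src/pvsignal/dispro.py` — 2×2 statistics, `DisproportionalityModel` / `SignalScreenResults`
- `src/pvsignal/profiling.py` — demographics, time to onset, CRS overlap, SOC shares
- `src/pvsignal/synth.py` — synthetic FAERS emulator and canned fixtures
- `src/pvsignal/pipeline.py`, `cli.py` — end-to-end orchestration and the `pv-signal` CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `docs/fixtures.md` — hand calculations behind the tiny fixtures
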