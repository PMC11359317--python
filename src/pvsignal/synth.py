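"""Synthetic FAERS-style data with known ground truth.

Emulates the six-table relational structure of FAERS quarterly extracts —
duplicate case versions, partial/missing dates, drug role codes — with
drug–event associations planted on the odds scale, so that the odds ratio
a screening pipeline should recover is analytically known: for a planted
pair with multiplier *m*, the odds of the event among the product's cases
are *m* × background odds, hence the true case-level ROR equals *m*.

Every draw flows from one :class:`numpy.random.Generator` seeded by the
config, so identical configs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import CaseBundle
from .quarters import QuarterLabel, enumerate_quarters

__all__ = ["SynthConfig", "GroundTruth", "generate", "make_fixture", "FIXTURE_NAMES"]

FILLER_PT = "DRUG INEFFECTIVE"  # guarantees every case reports >= 1 event

#: Default event panel: (verbatim PT, background report rate, SOC).
DEFAULT_EVENTS: tuple[tuple[str, float, str], ...] = (
    ("CYTOKINE RELEASE SYNDROME", 0.010, "Immune system disorders"),
    ("ICANS", 0.005, "Nervous system disorders"),
    ("NEUROTOXICITY", 0.005, "Nervous system disorders"),
    ("PYREXIA", 0.050, "General disorders and administration site conditions"),
    ("HYPOTENSION", 0.030, "Vascular disorders"),
    ("BACTERIAL INFECTION", 0.010, "Infections and infestations"),
    ("PLATELET COUNT DECREASED", 0.010, "Investigations"),
    ("HYPOXIA", 0.008, "Respiratory, thoracic and mediastinal disorders"),
    ("HEADACHE", 0.040, "Nervous system disorders"),
    ("FATIGUE", 0.050, "General disorders and administration site conditions"),
)

#: Reporting-population margins loosely matching spontaneous-report cohorts.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"F": 0.30, "M": 0.49, "": 0.21},
    "age": {"<18": 0.06, "18-64": 0.33, ">=65": 0.27, "": 0.34},
    "reporter": {"MD": 0.55, "PH": 0.16, "OT": 0.10, "CN": 0.12, "": 0.07},
    "country": {
        "US": 0.55, "CA": 0.05, "DE": 0.06, "FR": 0.05, "GB": 0.04,
        "JP": 0.04, "CN": 0.01, "BR": 0.10, "": 0.10,
    },
}


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for the synthetic reporting universe."""

    n_cases: int = 20_000
    products: tuple[tuple[str, float], ...] = (
        ("CARPRODUCT A", 0.05),
        ("CARPRODUCT B", 0.03),
    )
    events: tuple[tuple[str, float, str], ...] = DEFAULT_EVENTS
    planted: tuple[tuple[str, str, float], ...] = (
        ("CARPRODUCT A", "CYTOKINE RELEASE SYNDROME", 10.0),
        ("CARPRODUCT B", "HYPOXIA", 5.0),
    )
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.10
    onset_median_days: float = 5.0  # log-normal location (median)
    onset_sigma: float = 1.0
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    n_background_drugs: int = 20
    start_quarter: str = "2017Q4"
    end_quarter: str = "2024Q1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        names = [p for p, _ in self.products]
        if len(set(names)) != len(names):
            raise ValueError("duplicate product names")
        for name, prev in self.products:
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence of {name!r} out of (0,1): {prev}")
        event_names = {e for e, _, _ in self.events}
        if len(event_names) != len(self.events):
            raise ValueError("duplicate event names")
        for pt, rate, _ in self.events:
            if not 0.0 < rate < 1.0:
                raise ValueError(f"background rate of {pt!r} out of (0,1): {rate}")
        for product, event, mult in self.planted:
            if product not in names:
                raise ValueError(f"planted pair references unknown product {product!r}")
            if event not in event_names:
                raise ValueError(f"planted pair references unknown event {event!r}")
            if mult < 0:
                raise ValueError("odds multiplier must be >= 0")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate out of [0,1)")
        if not 0.0 <= self.partial_date_rate < 1.0:
            raise ValueError("partial_date_rate out of [0,1)")
        if self.onset_median_days <= 0 or self.onset_sigma <= 0:
            raise ValueError("onset model parameters must be positive")
        for block, probs in self.demographics.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"demographic block {block!r} does not sum to 1")
        QuarterLabel.parse(self.start_quarter), QuarterLabel.parse(self.end_quarter)

    @property
    def product_names(self) -> dict[str, list[str]]:
        """Attribution mapping usable by the primary-suspect filter."""
        return {name: [name] for name, _ in self.products}


@dataclass
class GroundTruth:
    """What the generator actually planted, before duplication/corruption."""

    planted: pd.DataFrame  # product, event, multiplier
    cases: pd.DataFrame    # CASEID, products, events, onset_day

    def write_tsv(self, out_dir: Path | str) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.planted.to_csv(out_dir / "ground_truth_planted.tsv", sep="\t", index=False)
        self.cases.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)


def _joined_labels(matrix: np.ndarray, names: list[str]) -> pd.Series:
    """Row-wise ';'-joined names of the True columns (vectorized)."""
    out = pd.Series("", index=range(matrix.shape[0]), dtype=object)
    for j, name in enumerate(names):
        out = out.where(~matrix[:, j], out + (name + ";"))
    return out.str.rstrip(";")


def _date_strings(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array → YYYYMMDD strings."""
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")


def _degrade(dates: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Truncate masked YYYYMMDD strings to month/year precision or blank."""
    out = dates.astype(object)
    u = rng.random(mask.sum())
    idx = np.flatnonzero(mask)
    for i, ui in zip(idx, u):
        s = out[i]
        out[i] = s[:6] if ui < 0.5 else (s[:4] if ui < 0.75 else "")
    return out


def generate(
    config: SynthConfig, out_dir: Path | str | None = None
) -> tuple[CaseBundle, GroundTruth]:
    """Draw one synthetic universe; optionally write FAERS-dialect files.

    Returns the raw (pre-deduplication) bundle — duplicate case versions
    re-emit a case's rows under a later FDA_DT and a higher PRIMARYID —
    plus the ground truth of what was planted.  Identifier columns are
    int64 in memory; they serialize to the same digits the text dialect
    carries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    caseids = np.arange(10_000_001, 10_000_001 + n, dtype=np.int64)
    pids = caseids * 10 + 1      # version 1
    pids2 = caseids * 10 + 2     # duplicate re-emission, strictly higher

    # --- product membership (independent Bernoulli per product) ------------
    prod_names = [p for p, _ in config.products]
    membership = np.column_stack(
        [rng.random(n) < prev for _, prev in config.products]
    ) if prod_names else np.zeros((n, 0), dtype=bool)

    # --- events on the odds scale ------------------------------------------
    mult = {(p, e): m for p, e, m in config.planted}
    event_names = [e for e, _, _ in config.events]
    E = np.zeros((n, len(event_names)), dtype=bool)
    for j, (pt, rate, _) in enumerate(config.events):
        odds = rate / (1.0 - rate)
        m = np.ones(n)
        for k, pname in enumerate(prod_names):
            mm = mult.get((pname, pt))
            if mm is not None:
                m = np.where(membership[:, k], m * mm, m)
        p = m * odds / (1.0 + m * odds)
        E[:, j] = rng.random(n) < p

    # --- dates --------------------------------------------------------------
    quarters = enumerate_quarters(config.start_quarter, config.end_quarter)
    span_start = np.datetime64(f"{quarters[0].year}-{quarters[0].quarter * 3 - 2:02d}-01")
    last = quarters[-1]
    span_end = np.datetime64(f"{last.year}-{last.quarter * 3:02d}-28")
    span_days = int((span_end - span_start) / np.timedelta64(1, "D")) - 120
    start_dates = span_start + rng.integers(0, max(span_days, 1), n).astype("timedelta64[D]")
    onset_days = np.round(
        rng.lognormal(math.log(config.onset_median_days), config.onset_sigma, n)
    ).astype(np.int64)
    event_dates = start_dates + onset_days.astype("timedelta64[D]")
    fda_dates = event_dates + rng.integers(3, 90, n).astype("timedelta64[D]")

    start_str = _date_strings(start_dates)
    event_str = _date_strings(event_dates)
    fda_str = _date_strings(fda_dates).astype(object)
    event_str = _degrade(event_str, rng.random(n) < config.partial_date_rate, rng)
    start_str = _degrade(start_str, rng.random(n) < config.partial_date_rate, rng)

    # --- demographics --------------------------------------------------------
    def draw(block: str) -> np.ndarray:
        cats = np.array(list(config.demographics[block]), dtype=object)
        probs = np.array([config.demographics[block][c] for c in cats], dtype=float)
        return cats[rng.choice(len(cats), size=n, p=probs / probs.sum())]

    sex = draw("sex")
    age_cat = draw("age")
    age = np.full(n, "", dtype=object)
    lo_hi = {"<18": (1, 17), "18-64": (18, 64), ">=65": (65, 90)}
    for cat, (lo, hi) in lo_hi.items():
        m_ = age_cat == cat
        age[m_] = rng.integers(lo, hi + 1, int(m_.sum())).astype(str)
    age_cod = np.where(age == "", "", "YR").astype(object)
    occp = draw("reporter")
    country = draw("country")

    # --- duplicate re-emissions (decided up front, applied per table) --------
    dup_member = rng.random(n) < config.duplicate_rate
    dup_lag = rng.integers(1, 90, n).astype("timedelta64[D]")
    fda2_str = _date_strings(fda_dates + dup_lag).astype(object)

    def emit(ridx: np.ndarray, cols: dict[str, np.ndarray], demo_cols: bool = False
             ) -> pd.DataFrame:
        """One table: original rows plus re-emitted rows for duplicate cases."""
        sel = dup_member[ridx]
        full = np.concatenate([ridx, ridx[sel]])
        out = {
            "PRIMARYID": np.concatenate([pids[ridx], pids2[ridx[sel]]]),
            "CASEID": caseids[full],
        }
        for name, col in cols.items():
            arr = col[ridx] if len(col) == n else col  # per-case vs per-row
            out[name] = np.concatenate([arr, arr[sel]])
        if demo_cols:
            out["FDA_DT"] = np.concatenate([fda_str[ridx], fda2_str[ridx[sel]]])
            out["CASEVERSION"] = np.concatenate(
                [np.full(len(ridx), "1", dtype=object), np.full(int(sel.sum()), "2", dtype=object)]
            )
        return pd.DataFrame(out)

    all_rows = np.arange(n)
    demo = emit(
        all_rows,
        {
            "EVENT_DT": event_str,
            "AGE": age,
            "AGE_COD": age_cod,
            "SEX": sex,
            "OCCP_COD": occp,
            "OCCR_COUNTRY": country,
        },
        demo_cols=True,
    )
    demo = demo[
        ["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "EVENT_DT",
         "AGE", "AGE_COD", "SEX", "OCCP_COD", "OCCR_COUNTRY"]
    ]

    # --- drug exposures ------------------------------------------------------
    on_any = membership.any(axis=1) if prod_names else np.zeros(n, dtype=bool)
    bg_idx = rng.integers(1, config.n_background_drugs + 1, n)
    bg_names = np.array(
        [f"BACKGROUND DRUG {i}" for i in range(config.n_background_drugs + 1)],
        dtype=object,
    )
    seq_after_products = membership.cumsum(axis=1) if prod_names else np.zeros((n, 0))
    idx_parts, seq_parts, role_parts, name_parts, ai_parts = [], [], [], [], []
    for k, pname in enumerate(prod_names):
        hit = np.flatnonzero(membership[:, k])
        idx_parts.append(hit)
        seq_parts.append(seq_after_products[hit, k])
        role_parts.append(np.full(len(hit), "PS", dtype=object))
        name_parts.append(np.full(len(hit), pname, dtype=object))
        ai_parts.append(np.full(len(hit), pname, dtype=object))
    bg_hit = np.flatnonzero(~on_any)
    idx_parts.append(bg_hit)
    seq_parts.append(np.ones(len(bg_hit), dtype=np.int64))
    role_parts.append(np.full(len(bg_hit), "PS", dtype=object))
    name_parts.append(bg_names[bg_idx[bg_hit]])
    ai_parts.append(np.full(len(bg_hit), "", dtype=object))
    conco = np.flatnonzero(rng.random(n) < 0.3)
    n_ps = (membership.sum(axis=1) + ~on_any).astype(np.int64)
    idx_parts.append(conco)
    seq_parts.append(n_ps[conco] + 1)
    role_parts.append(np.full(len(conco), "C", dtype=object))
    name_parts.append(bg_names[1 + (bg_idx[conco] % config.n_background_drugs)])
    ai_parts.append(np.full(len(conco), "", dtype=object))
    ridx = np.concatenate(idx_parts).astype(np.int64)
    seqs = np.concatenate(seq_parts).astype(np.int64)
    order = np.lexsort((seqs, ridx))
    drug = emit(
        ridx[order],
        {
            "DRUG_SEQ": seqs[order],
            "ROLE_COD": np.concatenate(role_parts)[order],
            "DRUGNAME": np.concatenate(name_parts)[order],
            "PROD_AI": np.concatenate(ai_parts)[order],
        },
    )

    # --- reactions ------------------------------------------------------------
    reac_case_idx: list[np.ndarray] = []
    reac_pts: list[np.ndarray] = []
    for j, pt in enumerate(event_names):
        hit = np.flatnonzero(E[:, j])
        reac_case_idx.append(hit)
        reac_pts.append(np.full(len(hit), pt, dtype=object))
    none_idx = np.flatnonzero(~E.any(axis=1))
    reac_case_idx.append(none_idx)
    reac_pts.append(np.full(len(none_idx), FILLER_PT, dtype=object))
    ridx = np.concatenate(reac_case_idx)
    pts = np.concatenate(reac_pts)
    order = np.argsort(ridx, kind="stable")
    reac = emit(ridx[order], {"PT": pts[order]})

    # --- therapy (start date of the first PS drug) ----------------------------
    ther = emit(
        all_rows,
        {
            "DSG_DRUG_SEQ": np.ones(n, dtype=np.int64),
            "START_DT": start_str,
            "END_DT": np.full(n, "", dtype=object),
        },
    )

    # --- outcomes --------------------------------------------------------------
    serious = rng.random(n) < 0.9
    code_pool = np.array(["HO", "DE", "LT", "DS"], dtype=object)
    code_choice = code_pool[rng.choice(4, size=n, p=[0.55, 0.25, 0.12, 0.08])]
    other = rng.random(n) < 0.5
    s_idx = np.flatnonzero(serious)
    ot_idx = np.flatnonzero(other | ~serious)
    o_idx = np.concatenate([s_idx, ot_idx])
    o_codes = np.concatenate(
        [code_choice[s_idx], np.full(len(ot_idx), "OT", dtype=object)]
    )
    order = np.argsort(o_idx, kind="stable")
    outc = emit(o_idx[order], {"OUTC_COD": o_codes[order]})

    # --- indications ------------------------------------------------------------
    indi_pt = np.where(on_any, "B-CELL LYMPHOMA", "PAIN").astype(object)
    indi = emit(
        all_rows,
        {"INDI_DRUG_SEQ": np.ones(n, dtype=np.int64), "INDI_PT": indi_pt},
    )

    bundle = CaseBundle(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc, indi=indi)

    truth = GroundTruth(
        planted=pd.DataFrame(list(config.planted), columns=["product", "event", "multiplier"]),
        cases=pd.DataFrame(
            {
                "CASEID": caseids,
                "products": _joined_labels(membership, prod_names),
                "events": _joined_labels(E, event_names),
                "onset_day": onset_days,
            }
        ),
    )

    if out_dir is not None:
        write_quarterly(bundle, out_dir, config)
        truth.write_tsv(out_dir)
    return bundle, truth


def write_quarterly(bundle: CaseBundle, out_dir: Path | str, config: SynthConfig) -> None:
    """Partition the bundle by FDA receipt quarter into FAERS-dialect files."""
    out_dir = Path(out_dir)
    quarters = enumerate_quarters(config.start_quarter, config.end_quarter)
    fda = pd.to_numeric(bundle.demo["FDA_DT"], errors="coerce").fillna(0).astype(int)
    q_of_row = (fda // 10000) * 10 + ((fda // 100) % 100 + 2) // 3
    keys = {q.year * 10 + q.quarter: q for q in quarters}
    last_key = max(keys)
    first_key = min(keys)
    q_clamped = q_of_row.clip(lower=first_key, upper=last_key)
    for key, quarter in keys.items():
        pid_sel = bundle.demo.loc[q_clamped == key, "PRIMARYID"]
        sub = bundle.restrict_to_primaryids(pid_sel)
        sub.write_faers(out_dir, quarter)


FIXTURE_NAMES = ("tiny-hand-checked", "null-universe", "planted-signals", "messy-dates")


def _tiny_hand_checked() -> CaseBundle:
    """12-case universe whose every downstream number is hand-enumerated.

    See docs/fixtures.md for the full hand calculations (2x2 cells, ROR,
    PRR, chi-square, onset arithmetic, CRS overlap, deduplication).
    """
    product = "TISAGENLECLEUCEL"
    # case -> (kept_pid, fda, extra versions)
    demo_rows = [
        # CASEID, PRIMARYID, FDA_DT, EVENT_DT
        ("100", "1001", "20230101", "20230115"),
        ("100", "1003", "20230301", "20230115"),   # later FDA_DT wins
        ("101", "1011", "20230215", "20230210"),
        ("101", "1015", "20230215", "20230210"),   # FDA_DT tie: higher id wins
        ("102", "1021", "20230110", "202302"),     # month-precision event date
        ("103", "1031", "20230120", "20230215"),
        ("104", "1041", "20230125", ""),           # missing event date
        ("105", "1051", "20230130", "20230208"),
        ("106", "1061", "20230201", "20230214"),
        ("107", "1071", "20230205", "20230310"),
        ("108", "1081", "20230210", "20230115"),
        ("109", "1091", "20230212", "20230116"),
        ("110", "1101", "20230214", "20230117"),
        ("111", "1111", "20230216", "20230118"),
    ]
    demo = pd.DataFrame(demo_rows, columns=["CASEID", "PRIMARYID", "FDA_DT", "EVENT_DT"])
    demo["CASEVERSION"] = "1"
    demo["AGE"] = ["10", "10", "30", "30", "70", "45", "", "50", "55", "60", "65", "40", "35", "25"]
    demo["AGE_COD"] = "YR"
    demo["SEX"] = ["F", "F", "M", "M", "F", "M", "", "M", "F", "M", "F", "M", "F", "M"]
    demo["OCCP_COD"] = ["MD", "MD", "PH", "PH", "CN", "MD", "", "MD", "CN", "MD", "MD", "PH", "CN", "MD"]
    demo["OCCR_COUNTRY"] = ["US", "US", "DE", "DE", "JP", "US", "", "US", "FR", "CA", "US", "GB", "US", "CN"]
    demo = demo[
        ["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "EVENT_DT",
         "AGE", "AGE_COD", "SEX", "OCCP_COD", "OCCR_COUNTRY"]
    ].astype(str)

    pid_of = dict(zip(demo["CASEID"], demo["PRIMARYID"]))  # any version is fine below

    def rows_for(caseid: str):
        return demo.loc[demo["CASEID"] == caseid, "PRIMARYID"]

    product_cases = ["100", "101", "102", "103"]
    reac_map = {
        "100": ["CYTOKINE RELEASE SYNDROME", "HYPOTENSION"],
        "101": ["CYTOKINE STORM", "HYPOTENSION"],
        "102": ["PYREXIA", "HYPOTENSION"],
        "103": ["HEADACHE", "HYPOTENSION"],
        "104": ["CYTOKINE RELEASE SYNDROME", "HYPOTENSION"],
        "105": ["CYTOKINE STORM", "HYPOTENSION"],
        "106": ["HEADACHE", "HYPOTENSION"],
        "107": ["PYREXIA", "HYPOTENSION"],
        "108": ["FATIGUE"],
        "109": ["FATIGUE"],
        "110": ["HEADACHE"],
        "111": ["PYREXIA"],
    }
    start_map = {
        "100": "20230101",  # event 20230115 -> onset 14 days
        "101": "20230210",  # start == event -> onset 0
        "102": "20230101",  # event has month precision -> excluded(partial)
        "103": "20230301",  # event 20230215 before start -> excluded(negative)
        "104": "20230101",  # event missing -> excluded(missing)
        "105": "20230201",  # onset 7
        "106": "20230207",  # onset 7
        "107": "20230208",  # onset 30
        "108": "20230101",
        "109": "20230101",
        "110": "20230101",
        "111": "20230101",
    }
    drug_rows, reac_rows, ther_rows, outc_rows, indi_rows = [], [], [], [], []
    for caseid, pts in reac_map.items():
        name = product if caseid in product_cases else "IBUPROFEN"
        for pid in rows_for(caseid):
            drug_rows.append((pid, caseid, "1", "PS", name, name if caseid in product_cases else ""))
            for pt in pts:
                reac_rows.append((pid, caseid, pt))
            ther_rows.append((pid, caseid, "1", start_map[caseid], ""))
            outc_rows.append((pid, caseid, "HO" if caseid in product_cases else "OT"))
            indi_rows.append((pid, caseid, "1",
                              "B-CELL LYMPHOMA" if caseid in product_cases else "PAIN"))
    _ = pid_of
    return CaseBundle(
        demo=demo,
        drug=pd.DataFrame(drug_rows, columns=["PRIMARYID", "CASEID", "DRUG_SEQ",
                                              "ROLE_COD", "DRUGNAME", "PROD_AI"]).astype(str),
        reac=pd.DataFrame(reac_rows, columns=["PRIMARYID", "CASEID", "PT"]).astype(str),
        ther=pd.DataFrame(ther_rows, columns=["PRIMARYID", "CASEID", "DSG_DRUG_SEQ",
                                              "START_DT", "END_DT"]).astype(str),
        outc=pd.DataFrame(outc_rows, columns=["PRIMARYID", "CASEID", "OUTC_COD"]).astype(str),
        indi=pd.DataFrame(indi_rows, columns=["PRIMARYID", "CASEID", "INDI_DRUG_SEQ",
                                              "INDI_PT"]).astype(str),
    )


def _messy_dates() -> CaseBundle:
    """Four-case universe exercising every onset-exclusion branch once."""
    rows = [
        # CASEID, PID, FDA, EVENT_DT, START_DT, note
        ("200", "2001", "20230301", "20230115", "20230101"),  # retained, 14 days
        ("201", "2011", "20230301", "", "20230101"),          # missing event date
        ("202", "2021", "20230301", "202301", "20230101"),    # partial precision
        ("203", "2031", "20230301", "20230115", "20230201"),  # negative interval
    ]
    demo = pd.DataFrame(
        [(pid, cid, "1", fda, ev, "40", "YR", "M", "MD", "US")
         for cid, pid, fda, ev, _ in rows],
        columns=["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "EVENT_DT",
                 "AGE", "AGE_COD", "SEX", "OCCP_COD", "OCCR_COUNTRY"],
    ).astype(str)
    drug = pd.DataFrame(
        [(pid, cid, "1", "PS", "TISAGENLECLEUCEL", "TISAGENLECLEUCEL")
         for cid, pid, _, _, _ in rows],
        columns=["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    ).astype(str)
    reac = pd.DataFrame(
        [(pid, cid, "CYTOKINE RELEASE SYNDROME") for cid, pid, _, _, _ in rows],
        columns=["PRIMARYID", "CASEID", "PT"],
    ).astype(str)
    ther = pd.DataFrame(
        [(pid, cid, "1", start, "") for cid, pid, _, _, start in rows],
        columns=["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT", "END_DT"],
    ).astype(str)
    outc = pd.DataFrame(
        [(pid, cid, "HO") for cid, pid, _, _, _ in rows],
        columns=["PRIMARYID", "CASEID", "OUTC_COD"],
    ).astype(str)
    indi = pd.DataFrame(
        [(pid, cid, "1", "B-CELL LYMPHOMA") for cid, pid, _, _, _ in rows],
        columns=["PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT"],
    ).astype(str)
    return CaseBundle(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc, indi=indi)


def fixture_config(name: str) -> SynthConfig:
    """Canned generator configs for the sampled fixtures."""
    if name == "planted-signals":
        return SynthConfig(
            n_cases=4_000,
            products=(("CARPRODUCT A", 0.06), ("CARPRODUCT B", 0.05)),
            planted=(
                ("CARPRODUCT A", "CYTOKINE RELEASE SYNDROME", 25.0),
                ("CARPRODUCT B", "HYPOXIA", 20.0),
            ),
            seed=1234,
        )
    if name == "null-universe":
        return SynthConfig(
            n_cases=4_000,
            products=(("CARPRODUCT A", 0.06), ("CARPRODUCT B", 0.05)),
            planted=(),
            seed=1234,
        )
    raise ValueError(f"no generator config for fixture {name!r}")


def make_fixture(
    name: str, out_dir: Path | str | None = None
) -> tuple[CaseBundle, GroundTruth | None]:
    """Build one canned scenario (see :data:`FIXTURE_NAMES`)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "tiny-hand-checked":
        bundle, truth = _tiny_hand_checked(), None
    elif name == "messy-dates":
        bundle, truth = _messy_dates(), None
    else:
        bundle, truth = generate(fixture_config(name))
    if out_dir is not None:
        quarter = QuarterLabel(2023, 1)
        if truth is not None:
            write_quarterly(bundle, out_dir, fixture_config(name))
            truth.write_tsv(out_dir)
        else:
            bundle.write_faers(out_dir, quarter)
    return bundle, truth
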