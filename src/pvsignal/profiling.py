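"""Descriptive layers: cohort characterization, onset timing, CRS overlap.

Time to onset is the interval in days between the start of therapy
(THER.START_DT, earliest primary-suspect row) and the reported event date
(DEMO.EVENT_DT).  Pairs with a missing date, a partial-precision date or a
negative interval (event before therapy start) are excluded, each with an
explicit reason so that retained + excluded classes always telescope to
the candidate total.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dates import DateWithPrecision, Precision
from .faers_io import SERIOUS_OUTCOME_CODES, CaseBundle, normalize_age
from .meddra import bundled_path

__all__ = [
    "Onset",
    "OverlapSummary",
    "time_to_onset",
    "compute_onsets",
    "onset_binning",
    "crs_overlap",
    "soc_signal_distribution",
    "demographics_table",
    "load_region_map",
]

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("missing", "partial", "negative")

#: Grouped label covering cytokine release syndrome and cytokine storm.
DEFAULT_CRS_LABELS = frozenset({"Cytokine release syndrome"})


@dataclass(frozen=True)
class Onset:
    """Outcome of one onset computation: days, or an exclusion reason."""

    days: int | None
    reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.days is not None


def _mid_impute(d: DateWithPrecision) -> DateWithPrecision:
    """Mid-period day for a partial date (month → 15th, year → July 1)."""
    if d.precision is Precision.MONTH:
        return DateWithPrecision(d.value + 15, Precision.DAY)
    if d.precision is Precision.YEAR:
        return DateWithPrecision(d.value + 701, Precision.DAY)
    return d


def time_to_onset(
    start: DateWithPrecision,
    event: DateWithPrecision,
    impute_mid: bool = False,
) -> Onset:
    """Days from therapy start to event, or an exclusion marker.

    Exclusion is a value, never an exception: reasons are ``missing``
    (either date absent), ``partial`` (either date coarser than day
    precision; avoided when ``impute_mid`` maps partials to mid-period)
    and ``negative`` (event precedes start).
    """
    if start.is_missing or event.is_missing:
        return Onset(None, "missing")
    if impute_mid:
        start, event = _mid_impute(start), _mid_impute(event)
    if start.precision is not Precision.DAY or event.precision is not Precision.DAY:
        return Onset(None, "partial")
    delta = (event.date - start.date).days
    if delta < 0:
        return Onset(None, "negative")
    return Onset(delta)


def compute_onsets(
    bundle: CaseBundle,
    product_cases: Mapping[str, Iterable[str]],
    impute_mid: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-(case, product) onset days with full exclusion accounting.

    The therapy anchor is the earliest START_DT among the case's THER rows
    tied to primary-suspect drug rows (falling back to all THER rows when
    the sequence link is absent).  Returns the retained records frame
    (columns CASEID, product, days) and a tally where
    ``retained + missing + partial + negative == total``.
    """
    from .dates import MISSING_DATE, parse_faers_date

    demo = bundle.demo.drop_duplicates("CASEID").set_index("CASEID")
    event_dates = {cid: parse_faers_date(v) for cid, v in demo.get(
        "EVENT_DT", pd.Series("", index=demo.index)).items()}

    ther = bundle.ther
    drug = bundle.drug
    ps = drug[drug["ROLE_COD"].str.strip().str.upper() == "PS"]
    if "DSG_DRUG_SEQ" in ther.columns and "DRUG_SEQ" in drug.columns:
        keyed = ther.merge(
            ps[["PRIMARYID", "DRUG_SEQ"]],
            left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
            right_on=["PRIMARYID", "DRUG_SEQ"],
            how="inner",
        )
    else:
        keyed = ther[ther["PRIMARYID"].isin(ps["PRIMARYID"])]
    start_by_case: dict[str, DateWithPrecision] = {}
    for cid, raw in zip(keyed["CASEID"], keyed["START_DT"]):
        d = parse_faers_date(raw)
        if d.is_missing:
            continue
        prev = start_by_case.get(cid)
        if prev is None or d.value < prev.value:
            start_by_case[cid] = d

    rows = []
    tally = {"total": 0, "retained": 0, "missing": 0, "partial": 0, "negative": 0}
    for product, cases in product_cases.items():
        for cid in sorted(set(cases)):
            if cid not in demo.index:
                continue
            tally["total"] += 1
            start = start_by_case.get(cid, MISSING_DATE)
            onset = time_to_onset(start, event_dates.get(cid, MISSING_DATE),
                                  impute_mid=impute_mid)
            if onset.retained:
                tally["retained"] += 1
                rows.append((cid, product, onset.days))
            else:
                tally[onset.reason] += 1
    frame = pd.DataFrame(rows, columns=["CASEID", "product", "days"])
    return frame, tally


def onset_binning(
    days_values: Iterable[int], edges: Sequence[int] = (7, 30, 60)
) -> pd.DataFrame:
    """Counts and fractions per onset window (upper-inclusive edges).

    Default edges (7, 30, 60) give windows 0–7, 8–30, 31–60 and >60 days,
    so "within 7 days" means days ≤ 7.  Empty input yields all-zero
    counts, never a crash.
    """
    edges = list(edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = [f"0-{edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]}")
    values = np.asarray(list(days_values), dtype=float)
    counts = np.zeros(len(labels), dtype=int)
    if values.size:
        if (values < 0).any():
            raise ValueError("negative onset days should have been excluded upstream")
        idx = np.searchsorted(edges, values, side="left")
        # searchsorted(side="left") puts a value equal to an edge into that
        # edge's window, i.e. upper-inclusive bins
        for i in idx:
            counts[int(i)] += 1
    total = counts.sum()
    frac = counts / total if total else np.zeros(len(labels))
    return pd.DataFrame({"bin": labels, "count": counts, "fraction": frac})


@dataclass(frozen=True)
class OverlapSummary:
    """Share of an event's cases that also report cytokine release syndrome."""

    event_label: str
    n_event: int
    n_with_crs: int

    @property
    def rate(self) -> float | None:
        if self.n_event == 0:
            return None
        return self.n_with_crs / self.n_event


def crs_overlap(
    universe: pd.DataFrame,
    event_label: str,
    crs_labels: Iterable[str] = DEFAULT_CRS_LABELS,
) -> OverlapSummary:
    """Overlap of *event_label* cases with CRS in the incidence frame."""
    crs_labels = set(crs_labels)
    event_cases = set(universe.loc[universe["event"] == event_label, "CASEID"])
    crs_cases = set(universe.loc[universe["event"].isin(crs_labels), "CASEID"])
    return OverlapSummary(
        event_label, len(event_cases), len(event_cases & crs_cases)
    )


def soc_signal_distribution(
    signal_frame: pd.DataFrame,
    soc_map: Mapping[str, str] | None = None,
    denominator: str = "signals",
) -> pd.DataFrame:
    """Per-product share of positive signals by system organ class.

    ``denominator="signals"`` (default) divides by the product's positive
    signal count; ``"pairs"`` divides by all screened pairs instead.
    Products with no positive signal are omitted with a logged notice.
    """
    if denominator not in ("signals", "pairs"):
        raise ValueError(f"unknown denominator {denominator!r}")
    frame = signal_frame.copy()
    if soc_map is not None:
        frame["soc"] = frame["event"].map(lambda e: soc_map.get(e))
    if "soc" not in frame.columns:
        raise ValueError("no SOC information: pass soc_map or a frame with a soc column")
    unmapped = sorted(frame.loc[frame["soc"].isna() | (frame["soc"] == ""), "event"].unique())
    if unmapped:
        raise ValueError(f"event labels without a SOC mapping: {unmapped}")
    rows = []
    for product, sub in frame.groupby("product"):
        pos = sub[sub["is_signal"]]
        if pos.empty:
            logger.info("product %r has no positive signals; omitted", product)
            continue
        denom = len(pos) if denominator == "signals" else len(sub)
        by_soc = pos.groupby("soc").size()
        for soc, k in by_soc.items():
            rows.append((product, soc, int(k), k / denom))
    return pd.DataFrame(rows, columns=["product", "soc", "n_signals", "share"])


def load_region_map(path=None) -> dict[str, str]:
    """Country code → region lookup (editable TSV shipped with the package)."""
    if path is None:
        path = bundled_path("regions.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["country"].str.upper(), df["region"]))


_REPORTER_HP = {"MD", "PH", "HP", "OT", "RN"}
_REPORTER_CONSUMER = {"CN", "LW"}


def _reporter_category(code: str) -> str:
    code = code.strip().upper()
    if code in _REPORTER_HP:
        return "Health professional"
    if code in _REPORTER_CONSUMER:
        return "Consumer"
    return "Not specified"


def _age_category(years: float) -> str:
    if np.isnan(years):
        return "Not specified"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64"
    return ">=65"


OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other",
}


def demographics_table(
    bundle: CaseBundle,
    product_cases: Mapping[str, Iterable[str]],
    region_map: Mapping[str, str] | None = None,
    top_indications: int = 5,
) -> pd.DataFrame:
    """Cohort characterization per product (counts and percentages).

    Blocks: sex, age windows (<18, 18–64, ≥65, unspecified), reporter
    occupation, reporting region, indication, seriousness and outcome
    codes.  Within every block except ``outcome`` (multi-select by nature)
    the counts sum to the product's case total; percentages recompute from
    counts exactly before rounding.
    """
    if region_map is None:
        region_map = load_region_map()
    demo = bundle.demo.drop_duplicates("CASEID").set_index("CASEID")
    serious_cases = set(
        bundle.outc.loc[
            bundle.outc["OUTC_COD"].str.strip().str.upper().isin(SERIOUS_OUTCOME_CODES),
            "CASEID",
        ]
    )
    outc_codes = bundle.outc.assign(
        code=bundle.outc["OUTC_COD"].str.strip().str.upper()
    ).drop_duplicates(["CASEID", "code"])
    indi = bundle.indi.drop_duplicates(["CASEID", "INDI_PT"]) if not bundle.indi.empty else bundle.indi

    rows = []

    def emit(product: str, block: str, counts: Mapping[str, int], total: int) -> None:
        for category, count in counts.items():
            pct = 100.0 * count / total if total else 0.0
            rows.append((product, block, category, int(count), pct))

    for product, cases in product_cases.items():
        ids = [c for c in set(cases) if c in demo.index]
        total = len(ids)
        sub = demo.loc[ids]

        sex = sub.get("SEX", pd.Series("", index=sub.index)).str.strip().str.upper()
        sex_cat = sex.map({"F": "Female", "M": "Male"}).fillna("Not specified")
        sex_cat[~sex.isin(["F", "M"])] = "Not specified"
        emit(product, "sex", sex_cat.value_counts().to_dict(), total)

        ages = [
            normalize_age(a, c)
            for a, c in zip(
                sub.get("AGE", pd.Series("", index=sub.index)),
                sub.get("AGE_COD", pd.Series("", index=sub.index)),
            )
        ]
        age_cat = pd.Series([_age_category(a) for a in ages], index=sub.index)
        emit(product, "age", age_cat.value_counts().to_dict(), total)

        occp = sub.get("OCCP_COD", pd.Series("", index=sub.index)).fillna("")
        emit(product, "reporter", occp.map(_reporter_category).value_counts().to_dict(), total)

        country = sub.get("OCCR_COUNTRY", pd.Series("", index=sub.index)).str.strip().str.upper()
        region = country.map(lambda c: region_map.get(c, "Not specified/other"))
        emit(product, "region", region.value_counts().to_dict(), total)

        if not indi.empty:
            mine = indi[indi["CASEID"].isin(ids)]
            per_case = mine.drop_duplicates("CASEID")  # first-listed indication
            top = per_case["INDI_PT"].value_counts().head(top_indications)
            counts = top.to_dict()
            counts["Not specified/other"] = total - int(top.sum())
            emit(product, "indication", counts, total)

        n_serious = len(set(ids) & serious_cases)
        emit(product, "seriousness",
             {"Serious": n_serious, "Non-serious": total - n_serious}, total)

        mine_outc = outc_codes[outc_codes["CASEID"].isin(ids)]
        oc = mine_outc["code"].map(lambda c: OUTCOME_LABELS.get(c, c)).value_counts()
        emit(product, "outcome", oc.to_dict(), total)

    return pd.DataFrame(rows, columns=["product", "block", "category", "count", "pct"])


def onset_by_event(onsets: pd.DataFrame, universe: pd.DataFrame) -> pd.DataFrame:
    """Attach event labels to per-case onset days (one row per case-event)."""
    return onsets.merge(universe[["CASEID", "event"]].drop_duplicates(), on="CASEID")
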