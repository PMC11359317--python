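"""Ingestion of FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System is distributed as quarterly packets
of "$"-delimited text tables (DEMO, DRUG, REAC, THER, OUTC, INDI) with one
header row.  This module parses those tables into a relational
:class:`CaseBundle`, restricts exposure to primary-suspect (PS) drug roles,
and collapses multiple submitted versions of a safety report to one row per
case (latest FDA receipt date, ties broken by the larger numeric PRIMARYID).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .dates import parse_faers_date
from .quarters import QuarterLabel

__all__ = [
    "CaseBundle",
    "SchemaError",
    "read_table",
    "read_quarter",
    "quarter_paths",
    "normalize_name",
    "filter_primary_suspect",
    "deduplicate",
    "normalize_age",
    "case_seriousness",
    "SERIOUS_OUTCOME_CODES",
]

logger = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_KINDS = ("demo", "drug", "reac", "ther", "outc", "indi")

#: Columns that must be present for a table to be usable at all.
REQUIRED_COLUMNS: dict[str, set[str]] = {
    "demo": {"PRIMARYID", "CASEID", "FDA_DT"},
    "drug": {"PRIMARYID", "CASEID", "DRUGNAME", "ROLE_COD"},
    "reac": {"PRIMARYID", "CASEID", "PT"},
    "ther": {"PRIMARYID", "CASEID", "START_DT"},
    "outc": {"PRIMARYID", "CASEID", "OUTC_COD"},
    "indi": {"PRIMARYID", "CASEID", "INDI_PT"},
}

DRUG_ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS outcome codes counted as serious; OT ("other") alone is not.
SERIOUS_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})


class SchemaError(ValueError):
    """A mandatory column is missing from a FAERS table."""


@dataclass
class CaseBundle:
    """The six FAERS entity tables for one or more quarters, as str frames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def concat(cls, bundles: Sequence["CaseBundle"]) -> "CaseBundle":
        if not bundles:
            raise ValueError("no bundles to concatenate")
        return cls(
            **{
                kind: pd.concat([b.tables()[kind] for b in bundles], ignore_index=True)
                for kind in TABLE_KINDS
            }
        )

    def restrict_to_primaryids(self, primaryids: Iterable[str]) -> "CaseBundle":
        keep = set(primaryids)
        return CaseBundle(
            **{
                kind: df[df["PRIMARYID"].isin(keep)].reset_index(drop=True)
                for kind, df in self.tables().items()
            }
        )

    def write_faers(self, out_dir: Path | str, quarter: QuarterLabel) -> dict[str, Path]:
        """Emit FAERS-dialect "$"-delimited files (DEMOyyQq.txt, ...)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for kind, df in self.tables().items():
            path = out_dir / f"{kind.upper()}{quarter.file_suffix}.txt"
            df.to_csv(path, sep=DELIMITER, index=False)
            paths[kind] = path
        return paths

    def write_tsv(self, out_dir: Path | str) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind, df in self.tables().items():
            path = out_dir / f"{kind}.tsv"
            df.to_csv(path, sep="\t", index=False)
            paths[kind] = path
        return paths

    @classmethod
    def read_tsv(cls, in_dir: Path | str) -> "CaseBundle":
        in_dir = Path(in_dir)
        return cls(
            **{
                kind: pd.read_csv(in_dir / f"{kind}.tsv", sep="\t", dtype=str,
                                  keep_default_na=False)
                for kind in TABLE_KINDS
            }
        )


def read_table(path: Path | str, kind: str) -> pd.DataFrame:
    """Read one "$"-delimited FAERS table as strings.

    Every non-header line yields one record; blank fields stay empty
    strings (dates are interpreted lazily downstream, so malformed values
    never crash the parse).
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    try:
        df = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read FAERS {kind.upper()} table at {path}: {exc}") from exc
    df.columns = [c.strip().upper() for c in df.columns]
    missing = REQUIRED_COLUMNS[kind] - set(df.columns)
    if missing:
        raise SchemaError(
            f"{kind.upper()} table {path} lacks mandatory columns: {sorted(missing)}"
        )
    logger.info("read %s: %d records from %s", kind.upper(), len(df), path)
    return df


def quarter_paths(faers_dir: Path | str, quarter: QuarterLabel) -> dict[str, Path]:
    """Expected file locations of one quarter's tables under *faers_dir*."""
    faers_dir = Path(faers_dir)
    return {
        kind: faers_dir / f"{kind.upper()}{quarter.file_suffix}.txt"
        for kind in TABLE_KINDS
    }


def read_quarter(table_paths: Mapping[str, Path | str]) -> CaseBundle:
    """Parse one quarter's six tables into a :class:`CaseBundle`."""
    frames = {}
    for kind in TABLE_KINDS:
        if kind not in table_paths:
            raise SchemaError(f"no path given for {kind.upper()} table")
        frames[kind] = read_table(table_paths[kind], kind)
    return CaseBundle(**frames)


def normalize_name(name: object) -> str:
    """Upper-case, trim and collapse internal whitespace (exact matching key)."""
    return " ".join(str(name).split()).upper()


def filter_primary_suspect(
    drug: pd.DataFrame, product_names: Mapping[str, Sequence[str]]
) -> dict[str, set[str]]:
    """Attribute cases to products via primary-suspect drug rows.

    A case belongs to a product iff at least one of its drug rows has
    role PS and a DRUGNAME or PROD_AI matching one of the product's
    synonyms after name normalization.  A case matching several products
    is attributed to each.  Returns CASEID sets keyed by product.
    """
    for product, names in product_names.items():
        if not names:
            raise ValueError(f"empty synonym list for product {product!r}")
    ps = drug[drug["ROLE_COD"].str.strip().str.upper() == "PS"]
    if ps.empty:
        return {product: set() for product in product_names}
    name_norm = ps["DRUGNAME"].map(normalize_name)
    ai_norm = (
        ps["PROD_AI"].map(normalize_name)
        if "PROD_AI" in ps.columns
        else pd.Series("", index=ps.index)
    )
    out: dict[str, set[str]] = {}
    for product, names in product_names.items():
        synonyms = {normalize_name(n) for n in names}
        hit = name_norm.isin(synonyms) | ai_norm.isin(synonyms)
        out[product] = set(ps.loc[hit, "CASEID"])
    return out


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Collapse report versions to one row per CASEID.

    Keeps the version with the latest FDA_DT; among equal receipt dates the
    numerically larger PRIMARYID wins.  Idempotent.  Raises ``ValueError``
    when a tie would need a non-numeric PRIMARYID as tiebreak.
    """
    if demo.empty:
        return demo.copy()
    fda = pd.to_numeric(demo["FDA_DT"], errors="coerce").fillna(-1)
    pid = pd.to_numeric(demo["PRIMARYID"], errors="coerce")
    dup_case = demo["CASEID"].duplicated(keep=False)
    if pid.isna().any():
        # non-numeric ids are only an error when actually needed to break a tie
        tied = demo.loc[dup_case].groupby("CASEID").size()
        bad = pid.isna() & dup_case
        if bad.any() and len(tied):
            raise ValueError(
                "PRIMARYID not numerically comparable for duplicated cases: "
                f"{sorted(demo.loc[bad, 'PRIMARYID'].head(5))}"
            )
    order = pd.DataFrame({"_fda": fda, "_pid": pid.fillna(-1)}, index=demo.index)
    idx = (
        order.assign(_case=demo["CASEID"].to_numpy())
        .sort_values(["_case", "_fda", "_pid"], kind="mergesort")
        .groupby("_case", sort=False)
        .tail(1)
        .index
    )
    kept = demo.loc[demo.index.isin(idx)].reset_index(drop=True)
    logger.info("deduplicate: %d versions -> %d cases", len(demo), len(kept))
    return kept


def dedup_bundle(bundle: CaseBundle) -> CaseBundle:
    """Deduplicate DEMO and restrict all tables to the surviving versions."""
    demo = deduplicate(bundle.demo)
    out = bundle.restrict_to_primaryids(demo["PRIMARYID"])
    out.demo = demo
    return out


_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}


def normalize_age(age: object, age_cod: object) -> float:
    """AGE + AGE_COD → age in years; out-of-range [0, 120] becomes NaN."""
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return float("nan")
    factor = _AGE_FACTORS.get(str(age_cod).strip().upper(), None)
    if factor is None:
        # FAERS leaves AGE_COD blank for the default unit (years)
        factor = 1.0 if str(age_cod).strip() == "" else None
    if factor is None:
        return float("nan")
    years = value * factor
    if not 0.0 <= years <= 120.0:
        return float("nan")
    return years


def case_seriousness(outc: pd.DataFrame) -> dict[str, bool]:
    """CASEID → serious?  Serious iff any outcome code in {DE,LT,HO,DS,CA,RI}."""
    codes = outc["OUTC_COD"].str.strip().str.upper()
    serious = outc.loc[codes.isin(SERIOUS_OUTCOME_CODES), "CASEID"]
    flags = dict.fromkeys(outc["CASEID"].unique(), False)
    flags.update(dict.fromkeys(serious.unique(), True))
    return flags


def parse_event_dates(demo: pd.DataFrame) -> pd.Series:
    """EVENT_DT column → Series of :class:`~pvsignal.dates.DateWithPrecision`."""
    col = demo["EVENT_DT"] if "EVENT_DT" in demo.columns else pd.Series("", index=demo.index)
    return col.map(parse_faers_date)
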