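"""Disproportionality statistics and MHRA-style signal screening.

For each (product, event) pair the analysis universe of deduplicated case
reports is collapsed to the classical 2×2 contingency table

    =============  ============  ============
                   target event  other events
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

from which the reporting odds ratio ``ROR = ad / bc`` with a log-normal
95% CI, the proportional reporting ratio ``PRR = [a/(a+b)] / [c/(c+d)]``
and Pearson's χ² are computed.  A pair is a *signal* when it jointly meets
the MHRA-style criteria: N = a ≥ 3, lower 95% CI bound of ROR > 1,
PRR > 2 and χ² > 4.  Screening results are ordered by descending ROR
within product.

The screening interface follows the Model/Results convention:
:class:`DisproportionalityModel` is built from case data and its
:meth:`~DisproportionalityModel.fit` returns a
:class:`SignalScreenResults` carrying estimates, intervals and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "SignalCriteria",
    "ZeroCellError",
    "DegenerateMarginError",
    "ror",
    "prr",
    "chi_square",
    "evaluate_signal",
    "build_contingency",
    "DisproportionalityModel",
    "SignalScreenResults",
    "screen_all",
]

logger = logging.getLogger(__name__)


class ZeroCellError(ValueError):
    """A 2×2 cell is zero where a positive count is required."""


class DegenerateMarginError(ValueError):
    """A margin of the 2×2 table is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the drug–event 2×2 table (unique-case counts)."""

    a: float  # target product AND target event
    b: float  # target product, other events
    c: float  # other products, target event
    d: float  # other products, other events

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def with_haldane(self) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: +0.5 to every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class SignalCriteria:
    """Joint signal thresholds: N ≥ min_n (non-strict), the rest strict."""

    min_n: int = 3
    ror_ci_low_gt: float = 1.0
    prr_gt: float = 2.0
    chi2_gt: float = 4.0

    def __post_init__(self) -> None:
        if min(self.min_n, self.ror_ci_low_gt, self.prr_gt, self.chi2_gt) <= 0:
            raise ValueError("all signal thresholds must be positive")


def ror(
    table: ContingencyTable, alpha: float = 0.05, correction: str = "none"
) -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal two-sided CI.

    ``ROR = ad/bc``; ``CI = exp(ln ROR ± z_{1−α/2} √(1/a+1/b+1/c+1/d))``.
    Zero cells raise :class:`ZeroCellError` unless ``correction`` is
    ``"haldane_half"``, which adds 0.5 to every cell first.
    """
    if correction not in ("none", "haldane_half"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "haldane_half":
        table = table.with_haldane()
    for name, cell in zip("abcd", table.cells()):
        if cell == 0:
            raise ZeroCellError(f"cell {name} is zero; ROR undefined without correction")
    a, b, c, d = table.cells()
    estimate = (a * d) / (b * c)
    z = sps.norm.ppf(1.0 - alpha / 2.0)  # exact quantile, not 1.96
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(estimate) - z * se), np.exp(np.log(estimate) + z * se)
    return float(estimate), float(lo), float(hi)


def prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``."""
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0:
        raise DegenerateMarginError("empty row margin; PRR undefined")
    if c == 0:
        raise ZeroCellError("cell c is zero; PRR undefined")
    return float((a / (a + b)) / (c / (c + d)))


def chi_square(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson χ² on the 2×2 table, optionally with Yates' correction.

    ``χ² = n(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)]``; Yates replaces
    ``|ad − bc|`` by ``max(0, |ad − bc| − n/2)``.
    """
    a, b, c, d = table.cells()
    n = table.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise DegenerateMarginError("zero margin; chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return float(n * diff * diff / margins)


def evaluate_signal(
    n: float,
    ci_low: float,
    prr_value: float,
    chi2: float,
    criteria: SignalCriteria | None = None,
) -> bool:
    """Joint MHRA-style verdict; NaN statistics never qualify."""
    crit = criteria or SignalCriteria()
    values = (n, ci_low, prr_value, chi2)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        return False
    return (
        n >= crit.min_n
        and ci_low > crit.ror_ci_low_gt
        and prr_value > crit.prr_gt
        and chi2 > crit.chi2_gt
    )


def build_contingency(
    universe: pd.DataFrame,
    product_cases: Iterable[str],
    event: str,
) -> ContingencyTable:
    """2×2 table for one (product, event) pair.

    *universe* is the deduplicated case → event-label incidence as a frame
    with columns ``CASEID`` and ``event`` (unique pairs, labels already
    grouped).  Cells count unique cases; margins are conserved by
    construction.
    """
    if universe.empty:
        raise ValueError("empty analysis universe")
    all_cases = set(universe["CASEID"])
    prod = set(product_cases) & all_cases
    if not prod:
        raise DegenerateMarginError("product has zero cases in the universe")
    event_cases = set(universe.loc[universe["event"] == event, "CASEID"])
    a = len(prod & event_cases)
    b = len(prod) - a
    c = len(event_cases) - a
    d = len(all_cases) - a - b - c
    return ContingencyTable(a, b, c, d)


def _screen_frame(
    universe: pd.DataFrame,
    product_cases: Mapping[str, Iterable[str]],
    events: Iterable[str] | None,
    criteria: SignalCriteria,
    alpha: float,
    correction: str,
    yates: bool,
    soc_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    if universe.empty:
        raise ValueError("empty analysis universe")
    pairs = universe.drop_duplicates(["CASEID", "event"])
    all_cases = pairs["CASEID"].unique()
    n_universe = len(all_cases)
    event_totals = pairs.groupby("event")["CASEID"].nunique()
    wanted = set(events) if events is not None else None

    rows = []
    for product, cases in product_cases.items():
        caseset = set(cases) & set(all_cases)
        n_prod = len(caseset)
        if n_prod == 0:
            logger.warning("product %r has no cases in the universe; skipped", product)
            continue
        mine = pairs[pairs["CASEID"].isin(caseset)]
        a_counts = mine.groupby("event")["CASEID"].nunique()
        for event, a in a_counts.items():
            if wanted is not None and event not in wanted:
                continue
            b = n_prod - a
            c = int(event_totals[event]) - int(a)
            d = n_universe - a - b - c
            table = ContingencyTable(int(a), int(b), int(c), int(d))
            row = {
                "product": product,
                "event": event,
                "n": int(a),
                "a": int(a),
                "b": int(b),
                "c": int(c),
                "d": int(d),
                "status": "ok",
                "ror": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "prr": np.nan,
                "chi2": np.nan,
            }
            try:
                row["ror"], row["ci_low"], row["ci_high"] = ror(
                    table, alpha=alpha, correction=correction
                )
            except ZeroCellError:
                row["status"] = "zero-cell"
            try:
                row["prr"] = prr(table)
            except (ZeroCellError, DegenerateMarginError):
                row["status"] = "zero-cell"
            try:
                row["chi2"] = chi_square(table, yates=yates)
            except DegenerateMarginError:
                row["status"] = "degenerate-margin"
            row["is_signal"] = evaluate_signal(
                row["n"], row["ci_low"], row["prr"], row["chi2"], criteria
            )
            rows.append(row)

    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    if soc_map is not None:
        frame.insert(2, "soc", frame["event"].map(lambda e: soc_map.get(e, "")))
    # ROR descending within product; NaN estimates sink; ties break on label
    frame = frame.sort_values(
        ["product", "ror", "event"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return frame


class DisproportionalityModel:
    """Disproportionality screen over a deduplicated reporting universe.

    Parameters
    ----------
    universe :
        Frame of (CASEID, event[, soc]) incidence pairs — one row per
        case-event, labels already normalized/grouped.
    product_cases :
        Mapping product → CASEID set attributed to it (primary-suspect).
    comparator :
        ``"full"`` screens each product against all other reports in the
        universe; ``"within-class"`` restricts the background to cases of
        the other listed products.
    """

    def __init__(
        self,
        universe: pd.DataFrame,
        product_cases: Mapping[str, Iterable[str]],
        comparator: str = "full",
    ) -> None:
        if comparator not in ("full", "within-class"):
            raise ValueError(f"unknown comparator {comparator!r}")
        if not {"CASEID", "event"} <= set(universe.columns):
            raise ValueError("universe needs CASEID and event columns")
        if universe.empty:
            raise ValueError("empty analysis universe")
        self.comparator = comparator
        self.product_cases = {p: set(c) for p, c in product_cases.items()}
        if comparator == "within-class":
            in_class = set().union(*self.product_cases.values()) if self.product_cases else set()
            universe = universe[universe["CASEID"].isin(in_class)]
        self.universe = universe.drop_duplicates(["CASEID", "event"]).reset_index(drop=True)
        self.soc_map: dict[str, str] | None = None
        if "soc" in universe.columns:
            self.soc_map = (
                universe.drop_duplicates("event").set_index("event")["soc"].to_dict()
            )

    @classmethod
    def from_bundle(
        cls,
        bundle,
        dictionary,
        product_names: Mapping[str, Iterable[str]],
        groups=None,
        comparator: str = "full",
    ) -> "DisproportionalityModel":
        """Build from a raw :class:`~pvsignal.faers_io.CaseBundle`.

        Deduplicates, attributes primary-suspect cases to products, and
        normalizes/groups reaction terms.
        """
        from .faers_io import dedup_bundle, filter_primary_suspect
        from .meddra import normalize_reactions

        clean = dedup_bundle(bundle)
        product_cases = filter_primary_suspect(clean.drug, product_names)
        universe = normalize_reactions(clean.reac, dictionary, groups)
        return cls(universe, product_cases, comparator=comparator)

    def fit(
        self,
        criteria: SignalCriteria | None = None,
        alpha: float = 0.05,
        correction: str = "none",
        yates: bool = False,
        events: Iterable[str] | None = None,
    ) -> "SignalScreenResults":
        criteria = criteria or SignalCriteria()
        frame = _screen_frame(
            self.universe,
            self.product_cases,
            events,
            criteria,
            alpha,
            correction,
            yates,
            self.soc_map,
        )
        return SignalScreenResults(self, frame, criteria, alpha)


class SignalScreenResults:
    """Per-(product, event) estimates with intervals and signal verdicts.

    ``frame`` holds full-precision values; :meth:`summary` renders the
    publication-style view (2 decimals, ROR-descending within product).
    """

    def __init__(
        self,
        model: DisproportionalityModel,
        frame: pd.DataFrame,
        criteria: SignalCriteria,
        alpha: float,
    ) -> None:
        self.model = model
        self.frame = frame
        self.criteria = criteria
        self.alpha = alpha

    @property
    def signals(self) -> pd.DataFrame:
        """Rows meeting the joint criteria."""
        if self.frame.empty:
            return self.frame
        return self.frame[self.frame["is_signal"]].reset_index(drop=True)

    def display_frame(self) -> pd.DataFrame:
        """Rounded (2-decimal) rendering of the estimates."""
        disp = self.frame.copy()
        for col in ("ror", "ci_low", "ci_high", "prr", "chi2"):
            if col in disp.columns:
                disp[col] = disp[col].round(2)
        return disp

    def summary(self) -> str:
        n_sig = 0 if self.frame.empty else int(self.frame["is_signal"].sum())
        lines = [
            "Disproportionality screen (ROR / PRR / chi-square, MHRA-style criteria)",
            f"universe: {self.model.universe['CASEID'].nunique()} cases, "
            f"{self.model.universe['event'].nunique()} event labels; "
            f"comparator: {self.model.comparator}",
            f"criteria: N>={self.criteria.min_n}, ROR CI low>{self.criteria.ror_ci_low_gt}, "
            f"PRR>{self.criteria.prr_gt}, chi2>{self.criteria.chi2_gt} "
            f"(alpha={self.alpha})",
            f"pairs screened: {len(self.frame)}; signals: {n_sig}",
            "",
        ]
        if not self.frame.empty:
            cols = [c for c in ("product", "event", "soc", "n", "ror", "ci_low",
                                "ci_high", "prr", "chi2", "is_signal") if c in self.frame.columns]
            lines.append(self.display_frame()[cols].to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path, machine_path=None) -> None:
        """Write the rounded table; optionally a full-precision twin."""
        self.display_frame().to_csv(path, sep="\t", index=False)
        if machine_path is not None:
            self.frame.to_csv(machine_path, sep="\t", index=False)


def screen_all(
    universe: pd.DataFrame,
    product_cases: Mapping[str, Iterable[str]],
    events: Iterable[str] | None = None,
    criteria: SignalCriteria | None = None,
    alpha: float = 0.05,
    correction: str = "none",
    yates: bool = False,
    comparator: str = "full",
) -> pd.DataFrame:
    """Functional wrapper: screen every (product, event) pair with a ≥ 1."""
    model = DisproportionalityModel(universe, product_cases, comparator=comparator)
    return model.fit(
        criteria=criteria, alpha=alpha, correction=correction, yates=yates, events=events
    ).frame
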