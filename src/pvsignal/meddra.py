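"""Preferred-term normalization, SOC attachment and composite term groups.

MedDRA is licensed and its content cannot ship here; the dictionary is a
user-supplied TSV (columns ``verbatim_pt``, ``current_pt``, ``soc``)
mapping event names as reported to the current preferred term and its
system organ class.  Composite event groups (e.g. "Tremor" covering
tremor, intention tremor, ...) and pathogen-type infection classes are
editable YAML configuration; the bundled files transcribe the groupings
used in the analysis this package reproduces.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml

from .faers_io import normalize_name

__all__ = [
    "TermDictionary",
    "TermGroup",
    "PathogenClassRule",
    "MappedTerm",
    "load_term_groups",
    "load_pathogen_rules",
    "normalize_pt",
    "apply_term_groups",
    "classify_infection",
    "bundled_path",
]

logger = logging.getLogger(__name__)

PATHOGEN_CLASSES = ("bacterial", "fungal", "viral")


def bundled_path(name: str) -> Path:
    """Path of a configuration file shipped with the package."""
    return Path(str(resources.files("pvsignal").joinpath("data", name)))


class MappedTerm(NamedTuple):
    """Result of a dictionary lookup; ``mapped`` is False for unknown terms."""

    current_pt: str
    soc: str
    mapped: bool


@dataclass
class TermDictionary:
    """Case-insensitive verbatim PT → (current PT, SOC) mapping."""

    version: str
    entries: dict[str, tuple[str, str]]
    unmapped_seen: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: Path | str, version: str | None = None) -> "TermDictionary":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"verbatim_pt", "current_pt", "soc"}
        if not required <= set(df.columns):
            raise ValueError(f"dictionary {path} must have columns {sorted(required)}")
        entries: dict[str, tuple[str, str]] = {}
        pt_soc: dict[str, str] = {}
        for verbatim, current, soc in df.itertuples(index=False):
            key = normalize_name(verbatim)
            entries[key] = (current, soc)
            prev = pt_soc.setdefault(current, soc)
            if prev != soc:
                raise ValueError(
                    f"current PT {current!r} maps to two SOCs: {prev!r} and {soc!r}"
                )
        return cls(version=version or str(path), entries=entries)

    def lookup(self, pt_verbatim: str) -> MappedTerm:
        return normalize_pt(pt_verbatim, self)


def normalize_pt(pt_verbatim: str, dictionary: TermDictionary) -> MappedTerm:
    """Map one verbatim PT through the dictionary.

    Unknown terms come back flagged (``mapped=False``) with the normalized
    verbatim as the term, and are tallied on the dictionary — never
    silently dropped.  An empty verbatim is a validation error.
    """
    key = normalize_name(pt_verbatim)
    if not key:
        raise ValueError("empty verbatim preferred term")
    hit = dictionary.entries.get(key)
    if hit is None:
        n = dictionary.unmapped_seen.get(key, 0) + 1
        dictionary.unmapped_seen[key] = n
        if n == 1:
            logger.warning("unmapped preferred term: %r", pt_verbatim)
        return MappedTerm(key, "", False)
    return MappedTerm(hit[0], hit[1], True)


@dataclass(frozen=True)
class TermGroup:
    """A named composite event and the current PTs it covers."""

    label: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term group {self.label!r} has no members")


def _validate_groups(groups: Iterable[TermGroup]) -> dict[str, str]:
    """Member PT (normalized) → group label; error on overlap."""
    mapping: dict[str, str] = {}
    labels: dict[str, str] = {}
    for g in groups:
        labels[normalize_name(g.label)] = g.label
        for pt in g.members:
            key = normalize_name(pt)
            if key in mapping and mapping[key] != g.label:
                raise ValueError(
                    f"PT {pt!r} belongs to both {mapping[key]!r} and {g.label!r}"
                )
            mapping[key] = g.label
    # a group's label may be its own member (Tremor includes tremor) but must
    # not be a member of a *different* group, or grouping would not be idempotent
    for label_key, label in labels.items():
        owner = mapping.get(label_key)
        if owner is not None and owner != label:
            raise ValueError(
                f"group label {label!r} is a member of group {owner!r}"
            )
    return mapping


def load_term_groups(path: Path | str | None = None) -> list[TermGroup]:
    """Load composite groups from YAML (label → {members, provenance})."""
    if path is None:
        path = bundled_path("term_groups.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = [
        TermGroup(
            label=label,
            members=frozenset(body["members"]),
            provenance=body.get("provenance", ""),
        )
        for label, body in raw.items()
    ]
    _validate_groups(groups)
    return groups


def apply_term_groups(
    case_pts: Iterable[str], groups: Iterable[TermGroup]
) -> set[str]:
    """Replace grouped PTs by their group label, set semantics.

    A case reporting several members of one group contributes that group
    label once; ungrouped PTs pass through unchanged.  Idempotent.
    """
    mapping = _validate_groups(groups)
    return {mapping.get(normalize_name(pt), pt) for pt in case_pts}


def group_mapping(groups: Iterable[TermGroup]) -> dict[str, str]:
    """Validated normalized-member → label mapping (for vectorized use)."""
    return _validate_groups(groups)


@dataclass(frozen=True)
class PathogenClassRule:
    """Infection PTs assigned to one pathogen type (bacterial/fungal/viral)."""

    class_label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.class_label not in PATHOGEN_CLASSES:
            raise ValueError(f"unknown pathogen class {self.class_label!r}")


def load_pathogen_rules(path: Path | str | None = None) -> list[PathogenClassRule]:
    if path is None:
        path = bundled_path("pathogen_classes.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = [
        PathogenClassRule(class_label=label, members=frozenset(members))
        for label, members in raw.items()
    ]
    seen: dict[str, str] = {}
    for r in rules:
        for pt in r.members:
            key = normalize_name(pt)
            if key in seen:
                raise ValueError(f"PT {pt!r} in both {seen[key]} and {r.class_label}")
            seen[key] = r.class_label
    return rules


def classify_infection(
    current_pt: str, rules: Iterable[PathogenClassRule]
) -> str | None:
    """Pathogen class of an infection PT, or None for uncovered terms."""
    key = normalize_name(current_pt)
    for rule in rules:
        if key in {normalize_name(m) for m in rule.members}:
            return rule.class_label
    return None


def normalize_reactions(
    reac, dictionary: TermDictionary, groups: Iterable[TermGroup] | None = None
):
    """Vectorized normalization of a REAC frame.

    Returns a frame with columns CASEID, event (grouped current PT or group
    label), soc, mapped — one row per unique (case, event).
    """
    import pandas as pd

    if reac.empty:
        return pd.DataFrame(columns=["CASEID", "event", "soc", "mapped"])
    uniq = reac["PT"].map(normalize_name).rename("key")
    lut = {}
    for key in uniq.unique():
        if not key:
            continue
        lut[key] = normalize_pt(key, dictionary)
    mapping = group_mapping(groups) if groups is not None else {}
    rows = []
    for caseid, key in zip(reac["CASEID"], uniq):
        if not key:
            continue
        term = lut[key]
        label = mapping.get(normalize_name(term.current_pt), term.current_pt)
        rows.append((caseid, label, term.soc, term.mapped))
    out = pd.DataFrame(rows, columns=["CASEID", "event", "soc", "mapped"])
    return out.drop_duplicates(["CASEID", "event"]).reset_index(drop=True)
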