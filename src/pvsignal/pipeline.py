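"""End-to-end orchestration: ingest → deduplicate → normalize → screen → profile.

A single :class:`PipelineConfig` (loadable from YAML) drives the stages;
:func:`run_pipeline` writes the publication-style outputs (signals,
demographics, onset bins, CRS overlap, SOC distribution) plus a JSON
manifest with per-stage record counts that telescope: raw versions in =
deduplicated cases + duplicate versions removed, and onset candidates =
retained + each exclusion class.  Identical configs produce byte-identical
output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import profiling
from .dispro import DisproportionalityModel, SignalCriteria
from .faers_io import CaseBundle, dedup_bundle, filter_primary_suspect, read_quarter, quarter_paths
from .meddra import TermDictionary, bundled_path, load_term_groups, normalize_reactions
from .quarters import enumerate_quarters
from .synth import SynthConfig, generate

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: Path
    quarters: tuple[str, str] = ("2017Q4", "2024Q1")
    faers_dir: Path | None = None
    synth: SynthConfig | None = None
    products_path: Path | None = None
    products: dict[str, list[str]] | None = None
    dict_path: Path | None = None
    groups_path: Path | None = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    comparator: str = "full"
    correction: str = "none"
    yates: bool = False
    alpha: float = 0.05
    bins: tuple[int, ...] = (7, 30, 60)
    impute_mid_dates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.faers_dir is None and self.synth is None:
            raise ValueError("either faers_dir or a synth config is required")
        if self.faers_dir is not None and not Path(self.faers_dir).is_dir():
            raise ValueError(f"faers_dir {self.faers_dir} does not exist")
        if self.synth is not None:
            self.synth.validate()
        if self.comparator not in ("full", "within-class"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        for p in (self.products_path, self.dict_path, self.groups_path):
            if p is not None and not Path(p).is_file():
                raise ValueError(f"configured path {p} does not exist")

    def resolved(self) -> dict:
        """JSON-serializable view of the configuration (for the manifest)."""

        def enc(v):
            if isinstance(v, Path):
                return str(v)
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, tuple):
                return [enc(x) for x in v]
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    """Read a pipeline config from YAML (keys mirror PipelineConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth = None
    if "synth" in raw and raw["synth"] is not None:
        s = dict(raw["synth"])
        for key in ("products", "events", "planted"):
            if key in s:
                s[key] = tuple(tuple(x) for x in s[key])
        synth = SynthConfig(**s)
    criteria = SignalCriteria(**raw.get("criteria", {}))
    kwargs = {
        k: raw[k]
        for k in (
            "comparator", "correction", "yates", "alpha", "impute_mid_dates", "seed",
        )
        if k in raw
    }
    return PipelineConfig(
        out_dir=Path(raw["out_dir"]),
        quarters=tuple(raw.get("quarters", ("2017Q4", "2024Q1"))),
        faers_dir=Path(raw["faers_dir"]) if raw.get("faers_dir") else None,
        synth=synth,
        products_path=Path(raw["products_path"]) if raw.get("products_path") else None,
        dict_path=Path(raw["dict_path"]) if raw.get("dict_path") else None,
        groups_path=Path(raw["groups_path"]) if raw.get("groups_path") else None,
        criteria=criteria,
        bins=tuple(raw.get("bins", (7, 30, 60))),
        **kwargs,
    )


def _load_products(config: PipelineConfig) -> dict[str, list[str]]:
    if config.products is not None:
        return config.products
    if config.synth is not None and config.products_path is None:
        return config.synth.product_names
    path = config.products_path or bundled_path("products.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": config.resolved()}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    t0 = time.perf_counter()

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s (t=%.2fs)", name, counts, time.perf_counter() - t0)

    # --- acquire -------------------------------------------------------------
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        bundle, _truth = generate(synth_cfg)
        stage("acquire", source="synthetic", demo_rows=len(bundle.demo))
    else:
        quarters = enumerate_quarters(*config.quarters)
        bundles = []
        for q in quarters:
            paths = quarter_paths(config.faers_dir, q)
            bundles.append(read_quarter(paths))
        bundle = CaseBundle.concat(bundles)
        stage("acquire", source=str(config.faers_dir), quarters=len(quarters),
              demo_rows=len(bundle.demo))

    # --- deduplicate ---------------------------------------------------------
    raw_versions = len(bundle.demo)
    clean = dedup_bundle(bundle)
    n_cases = len(clean.demo)
    stage("deduplicate", versions_in=raw_versions, cases=n_cases,
          duplicates_removed=raw_versions - n_cases)

    # --- attribute products --------------------------------------------------
    products = _load_products(config)
    product_cases = filter_primary_suspect(clean.drug, products)
    stage("attribute", **{p: len(c) for p, c in product_cases.items()})

    # --- normalize -----------------------------------------------------------
    dictionary = TermDictionary.from_tsv(
        config.dict_path or bundled_path("synthetic_pt_dictionary.tsv")
    )
    groups = load_term_groups(config.groups_path)
    universe = normalize_reactions(clean.reac, dictionary, groups)
    n_unmapped = int((~universe["mapped"]).sum()) if not universe.empty else 0
    stage("normalize", case_event_pairs=len(universe), unmapped_terms=n_unmapped)

    # --- screen --------------------------------------------------------------
    model = DisproportionalityModel(universe, product_cases, comparator=config.comparator)
    results = model.fit(
        criteria=config.criteria,
        alpha=config.alpha,
        correction=config.correction,
        yates=config.yates,
    )
    results.to_tsv(out_dir / "signals.tsv", out_dir / "signals_full.tsv")
    stage("screen", pairs=len(results.frame),
          signals=int(results.frame["is_signal"].sum()) if not results.frame.empty else 0)

    # --- profile -------------------------------------------------------------
    demo_table = profiling.demographics_table(clean, product_cases)
    demo_table.round({"pct": 4}).to_csv(out_dir / "demographics.tsv", sep="\t", index=False)

    onsets, tally = profiling.compute_onsets(
        clean, product_cases, impute_mid=config.impute_mid_dates
    )
    bins = profiling.onset_binning(onsets["days"], edges=config.bins)
    bins.to_csv(out_dir / "onset_bins.tsv", sep="\t", index=False)
    stage("onset", **tally)

    target_cases = set().union(*product_cases.values()) if product_cases else set()
    target_universe = universe[universe["CASEID"].isin(target_cases)]
    overlap_rows = []
    crs_labels = set(profiling.DEFAULT_CRS_LABELS)
    if not target_universe.empty:
        for event in sorted(target_universe["event"].unique()):
            if event in crs_labels:
                continue
            s = profiling.crs_overlap(target_universe, event)
            overlap_rows.append((event, s.n_event, s.n_with_crs,
                                 "" if s.rate is None else round(s.rate, 6)))
    pd.DataFrame(
        overlap_rows, columns=["event", "n_event", "n_with_crs", "rate"]
    ).to_csv(out_dir / "overlap.tsv", sep="\t", index=False)

    if not results.frame.empty and results.frame["is_signal"].any():
        soc = profiling.soc_signal_distribution(results.frame)
        soc.round({"share": 6}).to_csv(out_dir / "soc_distribution.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=["product", "soc", "n_signals", "share"]).to_csv(
            out_dir / "soc_distribution.tsv", sep="\t", index=False
        )

    manifest["seed"] = config.seed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh, sort_keys=True)
    return manifest
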