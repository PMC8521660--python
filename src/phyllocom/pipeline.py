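"""End-to-end orchestration: preprocess -> overlap -> clustering -> drivers -> indval.

A :class:`PipelineConfig` (usually loaded from YAML) holds the input paths,
the fixed analysis constants (rarefaction depth, presence threshold,
iteration counts, permutations), declarative sample-group selectors over the
metadata fields, and one global seed from which every stage derives its own
seed stream.  :func:`run_pipeline` executes the stages in order, writes every
result as TSV into the output directory together with a JSON echo of the
configuration, and never mutates its inputs on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, drivers, indval, overlap, preprocess
from .preprocess import RarefactionPlan, ThresholdConfig
from .tables import (
    CountTable,
    SampleSheet,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_table,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration failed validation before any computation."""


@dataclass
class PipelineConfig:
    table: str = ""
    metadata: str = ""
    taxonomy: str | None = None
    outdir: str = "results"
    table_dialect: str = "dense_tsv"
    seed: int = 0

    min_sample_reads: int = 1000
    presence_threshold: int = 3
    derive_threshold_from_mock: bool = True
    mock_expected_asvs: list = field(default_factory=list)

    rarefaction_depth: int = 1084
    n_rarefactions: int = 1000

    overlap_step: int = 100
    overlap_replicates: int = 10
    overlap_top_fractions: list = field(default_factory=lambda: [0.10, 0.05])
    overlap_convergence_window: int = 5

    metric: str = "bray_curtis"
    n_boot: int = 1000
    support_threshold: float = 0.5
    # named clustering analyses: {name: {field: value-or-list, ...}}
    cluster_groups: dict = field(default_factory=dict)

    driver_target: dict = field(
        default_factory=lambda: {
            "location": "outside",
            "stage": "flowering",
            "habitat": "flower",
        }
    )
    driver_screen_samples: dict = field(
        default_factory=lambda: {"location": "outside", "stage": "flowering"}
    )
    driver_max_extra: int = 0
    n_null_draws: int = 1000

    indval_samples: dict = field(
        default_factory=lambda: {
            "location": "outside",
            "stage": "flowering",
            "habitat": ["rosette", "leaf_no_soil_contact", "flower"],
        }
    )
    indval_group_by: str = "habitat"
    indval_target_group: str = "flower"
    indval_min_relabund: float = 0.001
    indval_permutations: int = 10_000
    indval_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        if not self.table or not Path(self.table).exists():
            raise ConfigError(f"count table not found: {self.table!r}")
        if not self.metadata or not Path(self.metadata).exists():
            raise ConfigError(f"metadata not found: {self.metadata!r}")
        if self.taxonomy and not Path(self.taxonomy).exists():
            raise ConfigError(f"taxonomy not found: {self.taxonomy!r}")

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _stable_tag(name: str) -> int:
    return zlib.crc32(name.encode()) % (2**31)


def _seed_for(config: PipelineConfig, stage: str) -> int:
    """Stable per-stage 31-bit seed from the global seed (process-independent)."""
    ss = np.random.SeedSequence(entropy=(int(config.seed), _stable_tag(stage)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class LoadedStudy:
    table: CountTable
    sheet: SampleSheet
    taxonomy_names: dict


def load_inputs(config: PipelineConfig) -> LoadedStudy:
    config.validate_paths()
    table = read_count_table(config.table, config.table_dialect)
    sheet = read_metadata(config.metadata)
    missing = [s for s in table.sample_ids if s not in sheet]
    if missing:
        raise ConfigError(f"sample(s) missing metadata: {missing[:5]}")
    tax_names: dict = {}
    if config.taxonomy:
        for rec in read_taxonomy(config.taxonomy):
            tax_names[rec.asv_id] = ";".join(rec.lineage)
    return LoadedStudy(table, sheet, tax_names)


def stage_preprocess(
    config: PipelineConfig, study: LoadedStudy, outdir: Path
) -> tuple[CountTable, int]:
    """Control-ASV removal, presence-threshold derivation, small-sample filter.

    Returns the cleaned (unrarefied, unthresholded) table and the presence
    threshold to use downstream.
    """
    sheet = study.sheet
    negatives = [
        s for s in sheet.select(habitat="negative_control")
        if s in set(study.table.sample_ids)
    ]
    cleaned, removed_asvs = preprocess.remove_control_asvs(study.table, negatives)
    threshold = config.presence_threshold
    mocks = [
        s for s in sheet.select(habitat="mock_control")
        if s in set(cleaned.sample_ids)
    ]
    if config.derive_threshold_from_mock and mocks and config.mock_expected_asvs:
        try:
            threshold = preprocess.derive_presence_threshold(
                cleaned.row(mocks[0]), config.mock_expected_asvs
            )
            log.info("presence threshold derived from mock: %d reads", threshold)
        except ValueError as err:
            log.warning("mock threshold derivation failed (%s); using %d", err, threshold)
    cleaned = cleaned.drop_samples(mocks)
    cleaned, removed_samples = preprocess.filter_small_samples(
        cleaned, config.min_sample_reads
    )
    report = pd.DataFrame(
        [("asv_removed_all_controls", a) for a in removed_asvs]
        + [("sample_below_min_reads", s) for s in removed_samples]
        + [("presence_threshold", str(threshold))],
        columns=["event", "id"],
    )
    write_table(report, outdir / "preprocess_report.tsv", sort_by=None)
    return cleaned, threshold


def stage_overlap(
    config: PipelineConfig,
    table: CountTable,
    sheet: SampleSheet,
    threshold: int,
    outdir: Path,
) -> pd.DataFrame:
    """Outside-vs-growth-chamber pooled overlap, per soil treatment."""
    phyllo = ["rosette", "leaf_no_soil_contact", "flower"]
    curves = []
    summary_rows = []
    seed = _seed_for(config, "overlap")
    present = set(table.sample_ids)
    for k, tr in enumerate(("AG", "FO")):
        out_ids = [
            s for s in sheet.select(location="outside", treatment=tr, habitat=phyllo)
            if s in present
        ]
        gc_ids = [
            s
            for s in sheet.select(
                location="growth_chamber", treatment=tr, habitat=phyllo
            )
            if s in present
        ]
        if not out_ids or not gc_ids:
            log.warning("treatment %s lacks phyllosphere samples; skipped", tr)
            continue
        pool_out = overlap.pool_reads(table, out_ids)
        pool_gc = overlap.pool_reads(table, gc_ids)
        variants: list[tuple[str, overlap.ReadPool, overlap.ReadPool]] = [
            ("all", pool_out, pool_gc)
        ]
        # the top-fraction variants restrict the *outside* pool only: the
        # question is what share of the abundant outside taxa is chamber-
        # detectable, so the chamber pool stays complete
        for frac in config.overlap_top_fractions:
            top_out, share_out = overlap.restrict_to_top_fraction(pool_out, frac)
            variants.append((f"top{frac:g}", top_out, pool_gc))
            summary_rows.append(
                {
                    "treatment": tr,
                    "comparison": f"top{frac:g}_read_share",
                    "value": share_out,
                }
            )
        for name, pa, pb in variants:
            curve = overlap.incremental_overlap(
                pa,
                pb,
                step=config.overlap_step,
                replicates=config.overlap_replicates,
                seed=np.random.SeedSequence((seed, k, _stable_tag(name))),
            )
            cf = curve.frame()
            cf.insert(0, "comparison", name)
            cf.insert(0, "treatment", tr)
            curves.append(cf)
            summary_rows.append(
                {
                    "treatment": tr,
                    "comparison": name,
                    "value": curve.converged(config.overlap_convergence_window),
                }
            )
    if curves:
        write_table(pd.concat(curves), outdir / "overlap_curves.tsv", sort_by=None)
    summary = pd.DataFrame(summary_rows, columns=["treatment", "comparison", "value"])
    write_table(summary, outdir / "overlap_summary.tsv", sort_by=None)
    return summary


def stage_cluster(
    config: PipelineConfig,
    table: CountTable,
    sheet: SampleSheet,
    outdir: Path,
) -> pd.DataFrame:
    """Bootstrap + serial-rarefaction clade support for each configured group."""
    frames = []
    present = set(table.sample_ids)
    for name, selector in config.cluster_groups.items():
        ids = [s for s in sheet.select(**selector) if s in present]
        if len(ids) < 3:
            log.warning("cluster group %r has < 3 samples; skipped", name)
            continue
        sub = table.select_samples(ids)
        plan = RarefactionPlan(
            depth=config.rarefaction_depth,
            n_iterations=config.n_rarefactions,
            base_seed=_seed_for(config, f"rare:{name}"),
        )
        reference = preprocess.rarefy(
            sub, plan.depth, preprocess.iteration_seed(plan.base_seed, 0)
        )
        tree = clustering.cluster_table(reference, config.metric)
        boot = clustering.bootstrap_support(
            reference,
            config.n_boot,
            config.metric,
            seed=_seed_for(config, f"boot:{name}"),
        )
        rare = clustering.rarefaction_support(sub, plan, config.metric)
        frame = clustering.support_table(boot, rare, config.support_threshold)
        frame.insert(0, "analysis", name)
        frames.append(frame)
        newick = clustering.to_newick(tree, boot, rare)
        (outdir / f"dendrogram_{name}.nwk").write_text(newick + "\n")
    result = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["analysis", "clade", "size", "bootstrap_fraction",
                     "rarefaction_fraction", "supported"]
        )
    )
    write_table(result, outdir / "cluster_supports.tsv", sort_by=None)
    return result


def stage_drivers(
    config: PipelineConfig,
    table: CountTable,
    sheet: SampleSheet,
    taxonomy_names: Mapping[str, str],
    outdir: Path,
) -> tuple[drivers.DriverScreenResult, drivers.RemovalTestResult | None]:
    present = set(table.sample_ids)
    screen_ids = [
        s for s in sheet.select(**config.driver_screen_samples) if s in present
    ]
    target_ids = [s for s in sheet.select(**config.driver_target) if s in present]
    if len(target_ids) < 2 or len(screen_ids) <= len(target_ids):
        raise ConfigError(
            "driver screen needs >= 2 target samples and a proper superset "
            "of screen samples"
        )
    sub = table.select_samples(screen_ids)
    plan = RarefactionPlan(
        depth=config.rarefaction_depth,
        n_iterations=config.n_rarefactions,
        base_seed=_seed_for(config, "drivers"),
    )
    screen = drivers.identify_drivers(
        sub, target_ids, plan, max_extra=config.driver_max_extra
    )
    write_table(
        screen.frame(taxonomy_names or None), outdir / "driver_report.tsv"
    )
    validation = None
    if screen.candidates and len(screen.candidates) < sub.shape[1]:
        validation = drivers.validate_drivers(
            sub,
            screen.candidates,
            target_ids,
            plan,
            n_null_draws=config.n_null_draws,
            metric=config.metric,
            max_extra=config.driver_max_extra,
            seed=_seed_for(config, "null"),
        )
        write_table(
            pd.DataFrame([dataclasses.asdict(validation)]),
            outdir / "driver_validation.tsv",
            sort_by=None,
        )
    return screen, validation


def stage_indval(
    config: PipelineConfig,
    table: CountTable,
    sheet: SampleSheet,
    outdir: Path,
) -> pd.DataFrame:
    present = set(table.sample_ids)
    ids = [s for s in sheet.select(**config.indval_samples) if s in present]
    if len(ids) < 4:
        raise ConfigError("IndVal needs at least 4 samples")
    sub = table.select_samples(ids)
    rarefied = preprocess.rarefy(
        sub, config.rarefaction_depth, _seed_for(config, "indval-rarefy")
    )
    groups = {s: getattr(sheet[s], config.indval_group_by) for s in ids}
    result = indval.indval_analysis(
        rarefied,
        groups,
        config.indval_target_group,
        indval.IndValConfig(
            min_relabund=config.indval_min_relabund,
            n_permutations=config.indval_permutations,
            alpha=config.indval_alpha,
            seed=_seed_for(config, "indval"),
        ),
    )
    write_table(result, outdir / "indval_report.tsv")
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a summary dict of headline results."""
    study = load_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_echo.json").write_text(
        json.dumps(config.echo(), indent=2, default=str) + "\n"
    )
    summary: dict[str, Any] = {}
    cleaned, threshold = stage_preprocess(config, study, outdir)
    summary["n_samples"] = len(cleaned.sample_ids)
    summary["n_asvs"] = len(cleaned.asv_ids)
    summary["presence_threshold"] = threshold
    overlap_summary = stage_overlap(config, cleaned, study.sheet, threshold, outdir)
    summary["overlap"] = overlap_summary.to_dict("records")
    cluster_summary = stage_cluster(config, cleaned, study.sheet, outdir)
    summary["n_supported_clades"] = (
        int(cluster_summary["supported"].sum()) if len(cluster_summary) else 0
    )
    screen, validation = stage_drivers(
        config, cleaned, study.sheet, study.taxonomy_names, outdir
    )
    summary["n_driver_candidates"] = len(screen.candidates)
    if validation is not None:
        summary["targeted_removal_breaks_clade"] = (
            validation.targeted_removal_breaks_clade
        )
        summary["null_fraction_retaining_clade"] = (
            validation.null_fraction_retaining_clade
        )
    iv = stage_indval(config, cleaned, study.sheet, outdir)
    summary["n_indval_tested"] = int(len(iv))
    summary["n_indval_significant"] = int(iv["significant"].sum())
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=str) + "\n"
    )
    return summary
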