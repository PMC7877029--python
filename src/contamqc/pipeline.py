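"""End-to-end three-stage QC pipeline.

Fixed stage order: decontam-tier removals → taxonomy filter → prevalence-
structure-tier removals (between-run within each batch, between-batch, calls
unioned) → rarefaction → low-total taxon filter → relativization, followed
by a QC report: ICC of per-taxon batch means before/after cleaning,
PERMANOVA of batch on Bray-Curtis before/after, PCoA coordinates, core
taxa, and an optional univariable RDA against a metadata column.

All randomness (rarefaction, permutation tests) is driven by explicit
seeds, so a rerun with the same config reproduces the report exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import batch_structure, community, decontam, qc_metrics
from .feature_table import (
    FeatureTable,
    SampleRecord,
    TaxonAnnotation,
    filter_taxa_by_lineage,
    metadata_by_id,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    decontam_method: str = "either"
    decontam_threshold: float = 0.5
    k: float = 0.067
    detection_threshold: int = 1
    rarefaction_depth: int = 8000
    min_total_count: int = 60
    relativize_total: float = 8000.0
    rarefaction_seed: int = 0
    permutation_seed: int = 0
    n_permutations: int = 999
    run_between_run: bool = True
    rda_variable: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0 <= self.decontam_threshold <= 1:
            raise ValueError("decontam_threshold must be in [0, 1]")
        if not 0 <= self.k <= 1:
            raise ValueError("k must be in [0, 1]")
        if self.rarefaction_depth < 1 or self.min_total_count < 0:
            raise ValueError("invalid depth / min_total_count")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key: value config file; explicit keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class QcReport:
    """Everything the pipeline decided and measured, with provenance."""

    config: PipelineConfig
    stage_log: list[dict] = field(default_factory=list)
    decontam_calls: pd.DataFrame | None = None
    structure_between_batch: pd.DataFrame | None = None
    structure_between_run: pd.DataFrame | None = None
    structure_union: pd.DataFrame | None = None
    removals: dict[str, list[str]] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)
    icc_before: qc_metrics.IccResult | None = None
    icc_after: qc_metrics.IccResult | None = None
    icc_consistency_before: qc_metrics.IccResult | None = None
    icc_consistency_after: qc_metrics.IccResult | None = None
    permanova_before: community.PermutationTestResult | None = None
    permanova_after: community.PermutationTestResult | None = None
    pcoa_after: community.OrdinationResult | None = None
    pcoa_sample_ids: list[str] = field(default_factory=list)
    core: set[str] = field(default_factory=set)
    rda: community.PermutationTestResult | None = None
    notes: list[str] = field(default_factory=list)
    cleaned_table: FeatureTable | None = None
    relativized: pd.DataFrame | None = None

    def log_stage(self, stage: str, table: FeatureTable, removed: list[str]) -> None:
        self.stage_log.append(
            {"stage": stage, "n_taxa": table.n_taxa, "n_samples": table.n_samples,
             "n_removed_taxa": len(removed)}
        )
        if removed:
            self.removals[stage] = removed

    def summary(self) -> str:
        lines = ["contamqc pipeline report", "=" * 24]
        for entry in self.stage_log:
            lines.append(
                f"{entry['stage']:<28s} taxa={entry['n_taxa']:<6d} "
                f"samples={entry['n_samples']:<5d} removed_taxa={entry['n_removed_taxa']}"
            )
        if self.icc_before and self.icc_after:
            lines.append(
                f"ICC(agreement) mean rel. abundance: "
                f"{self.icc_before.value:.3f} -> {self.icc_after.value:.3f}"
            )
        if self.icc_consistency_before and self.icc_consistency_after:
            lines.append(
                f"ICC(consistency) mean rel. abundance: "
                f"{self.icc_consistency_before.value:.3f} -> {self.icc_consistency_after.value:.3f}"
            )
        if self.permanova_before and self.permanova_after:
            lines.append(
                f"PERMANOVA batch R^2: {self.permanova_before.r_squared:.4f} "
                f"(p={self.permanova_before.p_value:.4g}) -> "
                f"{self.permanova_after.r_squared:.4f} (p={self.permanova_after.p_value:.4g})"
            )
        if self.rda:
            lines.append(
                f"RDA [{self.config.rda_variable}]: F={self.rda.statistic:.3f} "
                f"R^2={self.rda.r_squared:.4f} p={self.rda.p_value:.4g}"
            )
        lines.append(f"core taxa: {len(self.core)}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.summary() + "\n")
        if self.decontam_calls is not None:
            decontam.write_calls(self.decontam_calls, out / "contaminants_decontam.tsv")
        if self.structure_between_batch is not None:
            self.structure_between_batch.to_csv(out / "structure_between_batch.tsv", sep="\t")
        if self.structure_between_run is not None and len(self.structure_between_run):
            self.structure_between_run.to_csv(out / "structure_between_run.tsv", sep="\t")
        if self.structure_union is not None:
            self.structure_union.to_csv(out / "contaminants_structure.tsv", sep="\t")
        if self.cleaned_table is not None:
            write_feature_table(self.cleaned_table, out / "cleaned_counts.tsv")
        if self.relativized is not None:
            self.relativized.to_csv(out / "relativized.tsv", sep="\t", index_label="taxon_id")
        if self.pcoa_after is not None:
            coords = pd.DataFrame(
                self.pcoa_after.coordinates,
                index=self.pcoa_sample_ids,
                columns=[f"PCo{i + 1}" for i in range(self.pcoa_after.coordinates.shape[1])],
            )
            coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame(self.stage_log).to_csv(out / "stage_log.tsv", sep="\t", index=False)


def _batch_r2(
    table: FeatureTable,
    metadata: Iterable[SampleRecord],
    config: PipelineConfig,
    rarefy_seed: int,
) -> tuple[community.PermutationTestResult | None, community.OrdinationResult | None, list[str]]:
    """Rarefy/relativize biological samples and run batch PERMANOVA + PCoA."""
    by_id = metadata_by_id(metadata)
    bio = [s for s in table.sample_ids if by_id[s].sample_type == "biological"]
    sub = table.subset_samples(bio)
    rare, _ = community.rarefy(sub, config.rarefaction_depth, rarefy_seed)
    if rare.n_samples < 4:
        return None, None, []
    rel = community.relativize(rare, config.relativize_total)
    d = community.bray_curtis(rel.to_numpy().T)
    batches = [by_id[s].batch for s in rare.sample_ids]
    if len(set(batches)) < 2 or min(pd.Series(batches).value_counts()) < 2:
        return None, None, []
    res = community.permanova(d, batches, config.n_permutations, config.permutation_seed)
    ord_res = community.pcoa(d)
    return res, ord_res, list(rare.sample_ids)


def run_pipeline(
    config: PipelineConfig,
    table: FeatureTable | None = None,
    metadata: list[SampleRecord] | None = None,
    annotations: list[TaxonAnnotation] | None = None,
) -> QcReport:
    """Run the full three-stage framework; inputs in memory or from paths."""
    config.validate()
    if table is None:
        if config.counts_path is None or config.metadata_path is None:
            raise ValueError("counts_path and metadata_path required when no in-memory input")
        table = read_feature_table(config.counts_path)
        metadata = read_metadata(config.metadata_path)
        if config.taxonomy_path:
            annotations = read_taxonomy(config.taxonomy_path)
    assert metadata is not None
    by_id = metadata_by_id(metadata)
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")

    report = QcReport(config=config)
    report.log_stage("input", table, [])
    current = table

    # batch-effect baseline before any removal
    report.permanova_before, _, _ = _batch_r2(
        current, metadata, config, config.rarefaction_seed
    )
    try:
        report.icc_before = qc_metrics.icc(
            qc_metrics.batch_pairing(current, metadata), "agreement"
        )
        report.icc_consistency_before = qc_metrics.icc(
            qc_metrics.batch_pairing(current, metadata), "consistency"
        )
    except ValueError as e:
        report.notes.append(f"ICC before cleaning unavailable: {e}")

    # ---- stage 1: decontam tier
    has_neg = any(by_id[s].sample_type == "negative_control" for s in current.sample_ids)
    has_dna = sum(
        1 for s in current.sample_ids
        if by_id[s].sample_type == "biological" and by_id[s].dna_concentration
    ) >= decontam.MIN_FREQUENCY_POINTS
    if has_neg or has_dna:
        calls = decontam.is_contaminant(
            current, metadata, config.decontam_method, config.decontam_threshold,
            config.detection_threshold,
        )
        report.decontam_calls = calls
        removed = decontam.contaminant_ids(calls)
        current = current.drop_taxa(removed)
        report.log_stage("decontam", current, removed)
        neg_batches = {by_id[s].batch for s in table.sample_ids
                       if by_id[s].sample_type == "negative_control"}
        all_batches = {by_id[s].batch for s in table.sample_ids
                       if by_id[s].sample_type == "biological"}
        if has_neg and neg_batches != all_batches:
            report.notes.append(
                f"negative controls available only for batch(es) {sorted(neg_batches)}; "
                "pooled controls used for the prevalence score"
            )
    else:
        report.notes.append(
            "decontam tier skipped: no negative controls and no DNA concentrations"
        )
        report.log_stage("decontam (skipped)", current, [])

    # ---- stage 2: taxonomy filter
    if annotations is not None:
        current, removed = filter_taxa_by_lineage(
            current, [a for a in annotations if a.taxon_id in set(current.taxon_ids)]
        )
        report.log_stage("taxonomy_filter", current, removed)
    else:
        report.log_stage("taxonomy_filter (skipped)", current, [])

    # ---- stage 3: prevalence-structure tier
    bio_batches = sorted({by_id[s].batch for s in current.sample_ids
                          if by_id[s].sample_type == "biological"})
    call_sets: dict[str, set[str]] = {}
    if config.run_between_run:
        run_parts = []
        for b in bio_batches:
            flagged, prov = batch_structure.pairwise_within_batch(
                current, metadata, b, config.k, config.detection_threshold
            )
            call_sets[f"between_run:{b}"] = flagged
            if len(prov):
                run_parts.append(prov)
        report.structure_between_run = (
            pd.concat(run_parts) if run_parts else pd.DataFrame()
        )
    if len(bio_batches) == 2:
        cmp = batch_structure.compare_batches(
            current, metadata, config.k, config.detection_threshold
        )
        report.structure_between_batch = cmp
        call_sets["between_batch"] = set(batch_structure.flagged_ids(cmp))
    elif len(bio_batches) > 2:
        report.notes.append(
            f"{len(bio_batches)} batches found; between-batch comparison needs exactly 2, skipped"
        )
    union = batch_structure.combine_calls(call_sets)
    report.structure_union = union
    removed = [t for t in current.taxon_ids if t in set(union.index)]
    current = current.drop_taxa(removed)
    report.log_stage("batch_structure", current, removed)

    # ---- stages 4-6: rarefy, low-count filter, relativize
    current, dropped = community.rarefy(
        current, config.rarefaction_depth, config.rarefaction_seed
    )
    report.dropped_samples = dropped
    report.log_stage("rarefaction", current, [])
    current, lc_report = community.filter_low_count(current, config.min_total_count)
    report.log_stage("low_count_filter", current, lc_report["removed_taxa"])
    report.cleaned_table = current
    report.relativized = community.relativize(current, config.relativize_total)

    # ---- QC after cleaning
    bio_after = [s for s in current.sample_ids if by_id[s].sample_type == "biological"]
    try:
        report.icc_after = qc_metrics.icc(
            qc_metrics.batch_pairing(current, metadata), "agreement"
        )
        report.icc_consistency_after = qc_metrics.icc(
            qc_metrics.batch_pairing(current, metadata), "consistency"
        )
    except ValueError as e:
        report.notes.append(f"ICC after cleaning unavailable: {e}")
    if len(bio_after) >= 4:
        rel_bio = report.relativized[bio_after]
        d = community.bray_curtis(rel_bio.to_numpy().T)
        batches = [by_id[s].batch for s in bio_after]
        if len(set(batches)) >= 2 and min(pd.Series(batches).value_counts()) >= 2:
            report.permanova_after = community.permanova(
                d, batches, config.n_permutations, config.permutation_seed
            )
        report.pcoa_after = community.pcoa(d)
        report.pcoa_sample_ids = bio_after
        report.core = community.core_taxa(current.subset_samples(bio_after))
        if config.rda_variable:
            values = [getattr(by_id[s], config.rda_variable, None) for s in bio_after]
            if any(v is None for v in values):
                report.notes.append(
                    f"RDA skipped: metadata field {config.rda_variable!r} missing for some samples"
                )
            else:
                report.rda = community.rda_univariable(
                    rel_bio.to_numpy().T, pd.Series(values),
                    config.n_permutations, config.permutation_seed,
                )

    # bookkeeping invariant: every input taxon is retained or removed exactly once
    n_removed = sum(len(v) for v in report.removals.values())
    assert table.n_taxa == report.cleaned_table.n_taxa + n_removed, "taxon bookkeeping broken"

    if config.out_dir:
        report.write(config.out_dir)
    return report
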