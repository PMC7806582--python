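"""ASV/sample quality-control cascade for low-biomass amplicon tables.

Stages, in fixed order: negative-control contaminant removal (prevalence
rule), low-depth sample removal, singleton/empty feature removal, then
taxonomy-based removal of domain-unassigned and organellar ASVs.  The order
matters for the per-stage removal counts and is therefore not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import FeatureTable, TAXONOMY_RANKS, logger


@dataclass
class FilterReport:
    """What one QC stage removed."""

    stage: str
    removed_feature_ids: list = field(default_factory=list)
    removed_sample_ids: list = field(default_factory=list)

    @property
    def features_removed(self) -> int:
        return len(self.removed_feature_ids)

    @property
    def samples_removed(self) -> int:
        return len(self.removed_sample_ids)

    def log(self) -> None:
        logger.info(
            "QC stage %r: removed %d features, %d samples (n = %d)",
            self.stage,
            self.features_removed,
            self.samples_removed,
            self.features_removed + self.samples_removed,
        )


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Tabular view of a report list, one row per stage, in applied order."""
    return pd.DataFrame(
        {
            "stage": [r.stage for r in reports],
            "features_removed": [r.features_removed for r in reports],
            "samples_removed": [r.samples_removed for r in reports],
            "removed_feature_ids": [",".join(r.removed_feature_ids) for r in reports],
            "removed_sample_ids": [",".join(r.removed_sample_ids) for r in reports],
        }
    )


def remove_control_contaminants(
    table: FeatureTable,
    meta: pd.DataFrame,
    prevalence_threshold: float = 0.5,
) -> tuple[FeatureTable, FilterReport]:
    """Drop ASVs prevalent across negative controls, then drop the controls.

    An ASV is a contaminant when its prevalence (fraction of negative-control
    samples with count > 0) is >= ``prevalence_threshold`` *and* it is present
    in at least one fecal (non-control) sample.  Presence/absence only;
    abundance is ignored.  With no controls present this is a warning no-op.
    """
    controls = [
        s
        for s in table.sample_ids
        if s in meta.index and bool(meta.at[s, "is_negative_control"])
    ]
    report = FilterReport(stage="control_contaminants")
    if not controls:
        logger.warning("no negative-control samples present; contaminant filter skipped")
        return table, report
    fecal = [s for s in table.sample_ids if s not in controls]
    ctrl_counts = table.counts.loc[controls]
    prevalence = (ctrl_counts > 0).mean(axis=0)
    in_fecal = (table.counts.loc[fecal] > 0).any(axis=0) if fecal else prevalence * 0 > 0
    contaminants = [
        f
        for f in table.feature_ids
        if prevalence[f] >= prevalence_threshold and bool(in_fecal[f])
    ]
    report.removed_feature_ids = contaminants
    report.removed_sample_ids = controls
    out = table.without_features(contaminants).without_samples(controls)
    report.log()
    return out, report


def remove_low_depth_samples(
    table: FeatureTable, min_reads: int = 1000
) -> tuple[FeatureTable, FilterReport]:
    """Drop samples with total reads strictly below ``min_reads``."""
    depths = table.sample_depths()
    shallow = depths.index[depths < min_reads].tolist()
    if len(shallow) == len(table.sample_ids):
        raise ValueError(
            f"all {len(shallow)} samples fall below {min_reads} reads; nothing left"
        )
    report = FilterReport(stage="low_depth_samples", removed_sample_ids=shallow)
    report.log()
    return table.without_samples(shallow), report


def remove_singletons(table: FeatureTable) -> tuple[FeatureTable, list[FilterReport]]:
    """Drop table-wide singleton ASVs (total count == 1) and empty columns.

    Returns two report lines so empty (all-zero) columns are accounted
    separately from true singletons.
    """
    totals = table.counts.sum(axis=0)
    singles = totals.index[totals == 1].tolist()
    empties = totals.index[totals == 0].tolist()
    reports = [
        FilterReport(stage="singletons", removed_feature_ids=singles),
        FilterReport(stage="empty_features", removed_feature_ids=empties),
    ]
    for r in reports:
        r.log()
    return table.without_features(singles + empties), reports


def remove_unassigned_and_organelles(
    table: FeatureTable, taxonomy: pd.DataFrame
) -> tuple[FeatureTable, FilterReport]:
    """Drop domain-unassigned ASVs and mitochondrial/chloroplastic lineages.

    A feature absent from the taxonomy table counts as domain-unassigned.
    Organelle matching is case-insensitive at any rank.
    """
    doomed = []
    for f in table.feature_ids:
        if f not in taxonomy.index:
            doomed.append(f)
            continue
        lineage = [str(v).strip().lower() for v in taxonomy.loc[f, list(TAXONOMY_RANKS)]]
        if lineage[0] == "" or "mitochondria" in lineage or "chloroplast" in lineage:
            doomed.append(f)
    report = FilterReport(stage="unassigned_and_organelles", removed_feature_ids=doomed)
    report.log()
    return table.without_features(doomed), report


def run_qc_cascade(
    table: FeatureTable,
    meta: pd.DataFrame,
    taxonomy: pd.DataFrame,
    prevalence_threshold: float = 0.5,
    min_reads: int = 1000,
) -> tuple[FeatureTable, list[FilterReport]]:
    """Apply all QC stages in fixed order; returns table + cumulative report."""
    reports: list[FilterReport] = []
    table, rep = remove_control_contaminants(table, meta, prevalence_threshold)
    reports.append(rep)
    table, rep = remove_low_depth_samples(table, min_reads)
    reports.append(rep)
    table, reps = remove_singletons(table)
    reports.extend(reps)
    table, rep = remove_unassigned_and_organelles(table, taxonomy)
    reports.append(rep)
    return table, reports
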