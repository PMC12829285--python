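"""End-to-end orchestration of the marker-discovery workflow.

Mirrors the study design: variance-filter the discovery cohort
(per-cohort flags, union removal), align the two CpG panels, test all
pairwise cluster contrasts for differential methylation, run the
resampled elastic-net consensus selection on the DMP union, and
validate the consensus markers by PAM re-clustering in both cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dmp import dmp_union
from .io import BetaMatrix, cluster_labels
from .pam import PamResult, pam_validate
from .preprocess import FilterReport, intersect_cohorts, variance_filter
from .selection import ConsensusSet, run_consensus_selection

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_report: FilterReport
    dmp_features: set
    dmp_records: pd.DataFrame
    model_records: list
    consensus: ConsensusSet
    pam_discovery: PamResult
    pam_replication: PamResult | None
    discovery_filtered: BetaMatrix
    replication_filtered: BetaMatrix | None
    discovery_labels: np.ndarray
    replication_labels: np.ndarray | None


def run_pipeline(
    discovery: BetaMatrix,
    sheet: pd.DataFrame,
    cfg: PipelineConfig,
    replication: BetaMatrix | None = None,
) -> PipelineResult:
    """Run filter -> DMP -> consensus selection -> PAM validation.

    ``sheet`` must cover every sample of both matrices. When a
    replication cohort is given, the two panels are intersected first
    and the variance filter sees both cohorts (union removal); PAM
    validation then runs in both cohorts with k = number of phenotype
    clusters present in each.
    """
    discovery = discovery.drop_missing_cpgs()
    disc_labels = cluster_labels(sheet, discovery.sample_ids)

    if replication is not None:
        replication = replication.drop_missing_cpgs()
        rep_labels = cluster_labels(sheet, replication.sample_ids)
        disc_shared, rep_shared, xreport = intersect_cohorts(discovery, replication)
        logger.info(
            "panel intersection: %d shared CpGs (%d / %d dropped)",
            xreport["n_shared"],
            xreport["n_dropped_a"],
            xreport["n_dropped_b"],
        )
        stacked = BetaMatrix(
            disc_shared.sample_ids + rep_shared.sample_ids,
            disc_shared.cpg_ids,
            np.vstack([disc_shared.values, rep_shared.values]),
        )
        groups = np.array(
            ["discovery"] * disc_shared.n_samples
            + ["replication"] * rep_shared.n_samples
        )
        _, report = variance_filter(
            stacked,
            cfg.variance_filter_low,
            cfg.variance_filter_high,
            cohorts=groups,
        )
        keep = [g for g in disc_shared.cpg_ids if g not in report.removed_ids]
        disc_f = disc_shared.select_cpgs(keep)
        rep_f = rep_shared.select_cpgs(keep)
    else:
        rep_labels = None
        rep_f = None
        disc_f, report = variance_filter(
            discovery, cfg.variance_filter_low, cfg.variance_filter_high
        )
    logger.info(
        "variance filter: %d in, %d removed low, %d removed high, %d retained",
        report.n_input,
        report.n_removed_low,
        report.n_removed_high,
        report.n_retained,
    )

    features, dmp_records = dmp_union(disc_f, disc_labels, fdr=cfg.dmp_fdr)
    logger.info("DMP union: %d CpGs significant in at least one contrast", len(features))

    model_records, consensus = run_consensus_selection(disc_f, disc_labels, features, cfg)
    logger.info(
        "consensus: %d/%d successful models, %d retained CpGs",
        consensus.n_successful,
        len(model_records),
        len(consensus.retained),
    )

    k_disc = len(set(disc_labels.tolist()))
    pam_disc = pam_validate(disc_f, consensus.retained, disc_labels, k_disc)
    pam_rep = None
    if rep_f is not None:
        k_rep = len(set(rep_labels.tolist()))
        pam_rep = pam_validate(rep_f, consensus.retained, rep_labels, k_rep)

    return PipelineResult(
        config=cfg,
        filter_report=report,
        dmp_features=features,
        dmp_records=dmp_records,
        model_records=model_records,
        consensus=consensus,
        pam_discovery=pam_disc,
        pam_replication=pam_rep,
        discovery_filtered=disc_f,
        replication_filtered=rep_f,
        discovery_labels=disc_labels,
        replication_labels=rep_labels,
    )
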