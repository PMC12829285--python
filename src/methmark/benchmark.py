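"""Desk-scale surrogates of the full study design, for validation runs.

These helpers run the complete discovery/replication workflow on
synthetic cohorts whose cluster structure, cohort sizes and effect
strengths emulate the study (four discovery clusters of 50/42/45/50,
three replication clusters of 49/51/46, 10% informative CpGs with a
0.25 beta shift at concentration 60), at problem sizes a single CPU
handles in minutes: a 2,000-CpG panel and 200 resampling splits, with
a coarse 3-point alpha grid and a 15-point lambda path per split.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig, substream
from .io import cluster_labels
from .pam import random_cpg_control
from .pipeline import run_pipeline
from .preprocess import variance_filter
from .simulate import SyntheticConfig, simulate_cohort_pair

__all__ = ["run_study_surrogate", "run_random_control_surrogate"]

#: desk-scale analysis settings (generator effect sizes stay at defaults)
SURROGATE_N_CPGS = 2000
SURROGATE_N_SPLITS = 200
SURROGATE_ALPHA_GRID = (0.1, 0.5, 1.0)
SURROGATE_N_LAMBDA = 15


def run_study_surrogate(
    seed: int,
    n_cpgs: int = SURROGATE_N_CPGS,
    n_splits: int = SURROGATE_N_SPLITS,
    alpha_grid=SURROGATE_ALPHA_GRID,
    n_lambda: int = SURROGATE_N_LAMBDA,
    delta: float | None = None,
) -> dict:
    """Full pipeline on one synthetic cohort pair; key metrics as a dict.

    Generator parameters stay at their defaults (the emulated study
    conditions) except the panel size, which is a runtime scale; pass
    ``delta`` to override the effect size (e.g. 0 for null calibration).
    """
    gen_kwargs = {"n_cpgs": n_cpgs, "seed": seed}
    if delta is not None:
        gen_kwargs["delta"] = delta
    scfg = SyntheticConfig(**gen_kwargs)
    disc, rep, sheet, truth = simulate_cohort_pair(scfg)
    pcfg = PipelineConfig(
        seed=seed,
        n_splits=n_splits,
        alpha_grid=tuple(alpha_grid),
        n_lambda=n_lambda,
    )
    result = run_pipeline(disc, sheet, pcfg, replication=rep)

    info = truth.informative_cpgs
    panel = set(result.discovery_filtered.cpg_ids)
    retained = result.consensus.retained
    recall = len(retained & info) / max(len(info & panel), 1)
    precision = len(retained & info) / max(len(retained), 1)
    accs = np.array([r.accuracy for r in result.model_records])
    bals = np.array([r.balanced_accuracy for r in result.model_records])
    return {
        "pam_discovery_accuracy": result.pam_discovery.matched_accuracy,
        "pam_replication_accuracy": result.pam_replication.matched_accuracy,
        "min_split_accuracy": float(accs.min()),
        "min_split_balanced_accuracy": float(bals.min()),
        "n_successful_models": result.consensus.n_successful,
        "n_consensus_cpgs": len(retained),
        "consensus_recall": recall,
        "consensus_precision": precision,
        "n_dmp_features": len(result.dmp_features),
        "n_splits": n_splits,
    }


def run_random_control_surrogate(
    seed: int,
    n_cpgs_panel: int = 20000,
    n_random: int = 1500,
    repeats: int = 15,
    k: int = 4,
) -> np.ndarray:
    """Random-CpG PAM control on a wide synthetic discovery panel.

    Simulates a discovery cohort over ``n_cpgs_panel`` CpGs (generator
    defaults otherwise), applies the variance filter, then clusters
    ``repeats`` random draws of ``n_random`` post-filter CpGs and
    returns the matched accuracies.
    """
    scfg = SyntheticConfig(n_cpgs=n_cpgs_panel, seed=seed)
    disc, _, sheet, _ = simulate_cohort_pair(scfg)
    labels = cluster_labels(sheet, disc.sample_ids)
    disc_f, _ = variance_filter(disc)
    return random_cpg_control(
        disc_f,
        labels,
        k,
        substream(seed, "random-control"),
        n_cpgs=n_random,
        repeats=repeats,
    )
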