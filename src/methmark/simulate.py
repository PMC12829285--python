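"""Synthetic paired discovery/replication methylation cohorts.

Emulates the study design the pipeline was built for: a four-cluster
discovery cohort (phenotype clusters 2, 3, 5, 6; n = 187) and a
three-cluster replication cohort restricted to the high-risk clusters
(3, 5, 6; n = 146). A fraction of CpGs is informative — each carries a
mean methylation shift of ``delta`` in exactly one target cluster —
while the rest share a common baseline across clusters. Beta values are
drawn from beta distributions parameterised by mean and concentration,
so noise respects the [0, 1] support of methylation fractions.

Additional realism knobs:

* detection floor/ceiling CpGs (all-cohort means < 5% or > 95%) that
  the variance filter must remove;
* partially overlapping CpG panels between cohorts, emulating two array
  generations that share most but not all probes;
* quantitative traits with genuine correlations to planted CpGs, built
  as cluster-dependent Gaussians plus a loading on the standardized
  mean methylation of a trait-specific CpG set.

Everything planted is recorded in a :class:`GroundTruth` ledger so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import substream
from .io import BetaMatrix, DISCOVERY_CLUSTERS, REPLICATION_CLUSTERS

__all__ = ["SyntheticConfig", "GroundTruth", "sample_beta", "simulate_cohort_pair"]


def sample_beta(mu: float, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` beta variates with mean ``mu`` and concentration ``kappa``.

    Shape parameters are ``a = mu * kappa`` and ``b = (1 - mu) * kappa``,
    giving variance ``mu (1 - mu) / (kappa + 1)``.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu must lie in (0, 1), got {mu}")
    if not kappa > 0.0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return rng.beta(mu * kappa, (1.0 - mu) * kappa, size=n)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the study's cohort design."""

    n_per_cluster_discovery: dict = field(
        default_factory=lambda: {2: 50, 3: 42, 5: 45, 6: 50}
    )
    n_per_cluster_replication: dict = field(
        default_factory=lambda: {3: 49, 5: 51, 6: 46}
    )
    n_cpgs: int = 5000
    frac_informative: float = 0.10
    delta: float = 0.25
    concentration: float = 60.0
    frac_floor_ceiling: float = 0.02
    extreme_concentration: float = 1000.0
    panel_overlap: float = 0.95
    n_traits: int = 10
    trait_link_strength: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_cluster_discovery.values()):
            raise ValueError("discovery cluster counts must be positive")
        if any(n <= 0 for n in self.n_per_cluster_replication.values()):
            raise ValueError("replication cluster counts must be positive")
        if not 0.0 <= self.frac_informative < 1.0:
            raise ValueError("frac_informative must lie in [0, 1)")
        if not set(self.n_per_cluster_discovery) <= set(DISCOVERY_CLUSTERS):
            raise ValueError("discovery clusters must be among {2, 3, 5, 6}")
        if not set(self.n_per_cluster_replication) <= set(REPLICATION_CLUSTERS):
            raise ValueError("replication clusters must be among {3, 5, 6}")
        if not 0.0 <= self.panel_overlap <= 1.0:
            raise ValueError("panel_overlap must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Ledger of everything the generator planted."""

    informative_cpgs: frozenset
    target_cluster: dict  # CpG id -> phenotype cluster it marks
    direction: dict  # CpG id -> "hyper" | "hypo"
    trait_loadings: dict  # trait name -> frozenset of CpG ids
    floor_ceiling_cpgs: frozenset

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cpg_id": g,
                "target_cluster": self.target_cluster[g],
                "direction": self.direction[g],
            }
            for g in sorted(self.informative_cpgs)
        ]
        return pd.DataFrame(rows, columns=["cpg_id", "target_cluster", "direction"])


# planted means are kept away from the hard bounds so every beta draw is
# well defined and floor/ceiling status stays unambiguous
_MEAN_CLIP = (0.02, 0.98)


def _plant_means(cfg: SyntheticConfig, rng: np.random.Generator):
    """Per-CpG, per-cluster mean methylation plus the truth ledger.

    Returns ``(cpg_ids, means, kappa, truth_parts)`` where ``means``
    maps every phenotype cluster to a length-``n_cpgs`` vector of
    planted means for the discovery panel and ``kappa`` holds per-CpG
    beta concentrations.
    """
    n = cfg.n_cpgs
    cpg_ids = np.array([f"cg{i:07d}" for i in range(n)])
    clusters = sorted(cfg.n_per_cluster_discovery)

    n_fc = int(round(cfg.frac_floor_ceiling * n))
    n_info = int(round(cfg.frac_informative * n))
    if n_fc + n_info > n:
        raise ValueError("floor/ceiling and informative fractions overlap the panel")

    perm = rng.permutation(n)
    fc_idx = perm[:n_fc]
    info_idx = perm[n_fc : n_fc + n_info]

    base = rng.uniform(0.2, 0.8, size=n)
    # floor/ceiling probes: half consistently unmethylated, half fully
    # methylated, with strongly compressed variance as at array detection
    # bounds, so "all values < 5%" (or "> 95%") holds at cohort size
    half = n_fc // 2
    base[fc_idx[:half]] = rng.uniform(0.005, 0.02, size=half)
    base[fc_idx[half:]] = rng.uniform(0.98, 0.995, size=n_fc - half)
    kappa = np.full(n, np.nan)
    kappa[fc_idx] = cfg.extreme_concentration

    means = {c: base.copy() for c in clusters}
    target = rng.choice(clusters, size=n_info)
    sign = rng.choice([-1.0, 1.0], size=n_info)
    for j, idx in enumerate(info_idx):
        shifted = np.clip(base[idx] + sign[j] * cfg.delta, *_MEAN_CLIP)
        if shifted == base[idx]:  # clipping ate the whole effect: flip it
            sign[j] = -sign[j]
            shifted = np.clip(base[idx] + sign[j] * cfg.delta, *_MEAN_CLIP)
        means[target[j]][idx] = shifted

    kappa = np.where(np.isnan(kappa), cfg.concentration, kappa)
    truth = {
        "informative": cpg_ids[info_idx],
        "target": {cpg_ids[idx]: int(target[j]) for j, idx in enumerate(info_idx)},
        "direction": {
            cpg_ids[idx]: ("hyper" if sign[j] > 0 else "hypo")
            for j, idx in enumerate(info_idx)
        },
        "floor_ceiling": cpg_ids[fc_idx],
    }
    return cpg_ids, means, kappa, truth


def _draw_cohort(cpg_ids, means, counts, kappa, prefix, rng):
    """Sample one cohort's beta matrix from planted cluster means.

    ``kappa`` is a per-CpG concentration vector (floor/ceiling probes
    are tighter than the bulk).
    """
    kappa = np.asarray(kappa, dtype=float)
    sample_ids, labels, blocks = [], [], []
    for c in sorted(counts):
        n_c = counts[c]
        mu = means[c]
        a = mu * kappa
        b = (1.0 - mu) * kappa
        blocks.append(rng.beta(a, b, size=(n_c, len(cpg_ids))))
        start = len(sample_ids)
        sample_ids += [f"{prefix}{start + i + 1:04d}" for i in range(n_c)]
        labels += [c] * n_c
    values = np.vstack(blocks)
    m = BetaMatrix(tuple(sample_ids), tuple(cpg_ids), values)
    return m, np.array(labels, dtype=int)


def _make_traits(cfg, m: BetaMatrix, labels, info_ids, rng):
    """Cluster-dependent Gaussian traits with loadings on planted CpGs."""
    clusters = sorted(set(labels.tolist()))
    traits = {}
    loadings = {}
    col = {g: i for i, g in enumerate(m.cpg_ids)}
    info_ids = [g for g in info_ids if g in col]
    for t in range(cfg.n_traits):
        name = f"trait_{t + 1:02d}"
        cluster_mean = {c: rng.normal(0.0, 1.0) for c in clusters}
        base = np.array([cluster_mean[c] for c in labels]) + rng.normal(
            0.0, 1.0, size=m.n_samples
        )
        if info_ids:
            k = max(1, len(info_ids) // max(cfg.n_traits, 1))
            chosen = rng.choice(info_ids, size=min(k, len(info_ids)), replace=False)
            sub = m.values[:, [col[g] for g in chosen]].mean(axis=1)
            z = (sub - sub.mean()) / (sub.std() if sub.std() > 0 else 1.0)
            base = base + cfg.trait_link_strength * z
            loadings[name] = frozenset(chosen.tolist())
        else:
            loadings[name] = frozenset()
        traits[name] = base
    return traits, loadings


def simulate_cohort_pair(cfg: SyntheticConfig):
    """Generate the paired cohorts and their truth ledger.

    Returns ``(discovery, replication, sheet, truth)``: two
    :class:`~methmark.io.BetaMatrix` objects, one combined sample sheet
    (cohort, cluster, age, sex, traits), and a :class:`GroundTruth`.

    The replication panel keeps a random ``panel_overlap`` fraction of
    the discovery CpGs and replaces the remainder with fresh
    replication-only (uninformative) probes, so the two panels must be
    intersected before cross-cohort analysis — as with two array
    generations.
    """
    rng_plant = substream(cfg.seed, "simulate/plant")
    cpg_ids, means, kappa, truth_parts = _plant_means(cfg, rng_plant)

    disc, disc_labels = _draw_cohort(
        cpg_ids,
        means,
        cfg.n_per_cluster_discovery,
        kappa,
        "D",
        substream(cfg.seed, "simulate/discovery"),
    )

    # replication panel: shared subset plus fresh uninformative probes
    rng_panel = substream(cfg.seed, "simulate/panel")
    n_shared = int(round(cfg.panel_overlap * cfg.n_cpgs))
    shared_idx = np.sort(rng_panel.choice(cfg.n_cpgs, size=n_shared, replace=False))
    n_new = cfg.n_cpgs - n_shared
    new_ids = np.array([f"cg2_{i:07d}" for i in range(n_new)])
    new_base = rng_panel.uniform(0.2, 0.8, size=n_new)

    rep_clusters = sorted(cfg.n_per_cluster_replication)
    rep_ids = np.concatenate([cpg_ids[shared_idx], new_ids])
    rep_means = {
        c: np.concatenate([means[c][shared_idx], new_base]) for c in rep_clusters
    }
    rep_kappa = np.concatenate([kappa[shared_idx], np.full(n_new, cfg.concentration)])
    rep, rep_labels = _draw_cohort(
        rep_ids,
        rep_means,
        cfg.n_per_cluster_replication,
        rep_kappa,
        "R",
        substream(cfg.seed, "simulate/replication"),
    )

    truth = GroundTruth(
        informative_cpgs=frozenset(truth_parts["informative"].tolist()),
        target_cluster=truth_parts["target"],
        direction=truth_parts["direction"],
        trait_loadings={},
        floor_ceiling_cpgs=frozenset(truth_parts["floor_ceiling"].tolist()),
    )

    rng_traits = substream(cfg.seed, "simulate/traits")
    disc_traits, disc_loadings = _make_traits(
        cfg, disc, disc_labels, sorted(truth.informative_cpgs), rng_traits
    )
    rep_traits, _ = _make_traits(
        cfg, rep, rep_labels, sorted(truth.informative_cpgs), rng_traits
    )
    truth = GroundTruth(
        informative_cpgs=truth.informative_cpgs,
        target_cluster=truth.target_cluster,
        direction=truth.direction,
        trait_loadings=disc_loadings,
        floor_ceiling_cpgs=truth.floor_ceiling_cpgs,
    )

    rng_cov = substream(cfg.seed, "simulate/covariates")
    rows = []
    for ids, labels, cohort, traits in (
        (disc.sample_ids, disc_labels, "discovery", disc_traits),
        (rep.sample_ids, rep_labels, "replication", rep_traits),
    ):
        for i, (sid, c) in enumerate(zip(ids, labels)):
            row = {
                "sample_id": sid,
                "cohort": cohort,
                "cluster": int(c),
                "age": float(np.round(rng_cov.normal(58.0, 8.0), 1)),
                "sex": str(rng_cov.choice(["female", "male"])),
            }
            for name, vec in traits.items():
                row[name] = float(vec[i])
            rows.append(row)
    sheet = pd.DataFrame(rows)
    return disc, rep, sheet, truth
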