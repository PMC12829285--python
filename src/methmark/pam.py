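"""Partitioning around medoids (PAM) and phenotype-label matching.

PAM is implemented as the classical BUILD + SWAP algorithm: BUILD
greedily seeds k medoids to minimise total distance-to-nearest-medoid;
SWAP repeatedly applies the single (medoid, non-medoid) exchange with
the largest strict cost reduction until no exchange helps. Distances
are Euclidean over the selected CpG columns, on raw beta values. The
algorithm is deterministic for a given input order; ties are broken by
the lowest sample index.

Because PAM labels are arbitrary, agreement with phenotype clusters is
scored after an optimal one-to-one label assignment (Hungarian method
on the confusion matrix, rectangular allowed): "matched accuracy" is
the fraction of samples whose PAM cluster maps onto their phenotype
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist

from .io import BetaMatrix

__all__ = ["PamResult", "pam_cluster", "match_labels", "random_cpg_control"]


@dataclass(frozen=True)
class PamResult:
    k: int
    medoid_ids: tuple
    assignment: dict  # sample id -> medoid index (0..k-1)
    total_cost: float
    confusion: np.ndarray | None = None
    label_map: dict | None = None
    matched_accuracy: float | None = None


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of improvements over current nearest
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = list(medoids)
    while True:
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            trial = medoids.copy()
            for h in range(n):
                if h in medoids:
                    continue
                trial[mi] = h
                new_cost = d[:, trial].min(axis=1).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
            trial[mi] = m
        if best[1] is None:
            return medoids
        medoids[best[1]] = best[2]


def pam_cluster(m: BetaMatrix, k: int) -> PamResult:
    """Cluster samples into ``k`` groups around medoids (BUILD + SWAP)."""
    n = m.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    if m.n_cpgs < 1:
        raise ValueError("need at least one CpG column")
    if k == n:
        medoids = list(range(n))
        assign_idx = np.arange(n)
        total = 0.0
    else:
        d = squareform(pdist(m.values, metric="euclidean"))
        medoids = sorted(_pam_swap(d, _pam_build(d, k)))
        dm = d[:, medoids]
        assign_idx = dm.argmin(axis=1)
        total = float(dm.min(axis=1).sum())
    assignment = {s: int(a) for s, a in zip(m.sample_ids, assign_idx)}
    return PamResult(
        k=k,
        medoid_ids=tuple(m.sample_ids[i] for i in medoids),
        assignment=assignment,
        total_cost=total,
    )


def match_labels(assignment, truth):
    """Optimal injective map from PAM clusters to phenotype clusters.

    ``assignment`` and ``truth`` are equal-length label vectors (or an
    assignment dict and a truth dict over the same samples). Returns
    ``(label_map, matched_accuracy, confusion)`` where ``label_map``
    sends each PAM cluster to the phenotype cluster maximising the
    total matched count (Hungarian assignment on the negated confusion
    matrix; rectangular confusion is allowed — surplus clusters on
    either side stay unmatched).
    """
    if isinstance(assignment, dict):
        if set(assignment) != set(truth):
            raise ValueError("assignment and truth cover different samples")
        keys = sorted(assignment)
        a = np.array([assignment[s] for s in keys])
        t = np.array([truth[s] for s in keys])
    else:
        a = np.asarray(assignment)
        t = np.asarray(truth)
        if a.shape != t.shape:
            raise ValueError("label vectors differ in length")
    if a.size == 0:
        raise ValueError("empty labelings")
    pam_levels = sorted(set(a.tolist()))
    true_levels = sorted(set(t.tolist()))
    confusion = np.zeros((len(pam_levels), len(true_levels)), dtype=int)
    for i, pl in enumerate(pam_levels):
        for j, tl in enumerate(true_levels):
            confusion[i, j] = int(((a == pl) & (t == tl)).sum())
    rows, cols = linear_sum_assignment(-confusion)
    label_map = {pam_levels[i]: true_levels[j] for i, j in zip(rows, cols)}
    matched = int(confusion[rows, cols].sum())
    return label_map, matched / a.size, confusion


def pam_validate(m: BetaMatrix, cpg_set, truth_labels, k: int) -> PamResult:
    """PAM on a CpG subset plus optimal matching against phenotype labels."""
    sub = m.select_cpgs(sorted(cpg_set))
    res = pam_cluster(sub, k)
    a = np.array([res.assignment[s] for s in sub.sample_ids])
    label_map, acc, confusion = match_labels(a, np.asarray(truth_labels))
    return PamResult(
        k=res.k,
        medoid_ids=res.medoid_ids,
        assignment=res.assignment,
        total_cost=res.total_cost,
        confusion=confusion,
        label_map=label_map,
        matched_accuracy=acc,
    )


def random_cpg_control(
    m: BetaMatrix,
    truth_labels,
    k: int,
    rng: np.random.Generator,
    n_cpgs: int = 1500,
    repeats: int = 15,
) -> np.ndarray:
    """Matched accuracies of PAM on random CpG subsets (null control).

    Each repeat draws ``n_cpgs`` CpGs uniformly without replacement from
    the post-filter panel of ``m`` and records the matched accuracy of
    PAM clustering on that subset.
    """
    panel = np.asarray(m.cpg_ids, dtype=object)
    if panel.size < n_cpgs:
        raise ValueError(
            f"panel of {panel.size} CpGs is smaller than the requested {n_cpgs}"
        )
    accs = np.empty(repeats)
    for r in range(repeats):
        subset = rng.choice(panel, size=n_cpgs, replace=False)
        res = pam_validate(m, subset.tolist(), truth_labels, k)
        accs[r] = res.matched_accuracy
    return accs
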