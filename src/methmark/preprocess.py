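"""Variance filtering and cross-cohort panel alignment.

The variance filter removes CpGs that are consistently unmethylated
(every value below ``low``) or consistently methylated (every value
above ``high``) within at least one cohort group; such probes carry
essentially no variability in blood and only add noise dimensions.
Flags are raised per cohort and the union is removed, so all cohorts
keep one shared feature space. Inequalities are strict: values exactly
at the thresholds are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BetaMatrix

__all__ = ["FilterReport", "variance_filter", "intersect_cohorts"]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_removed_low: int
    n_removed_high: int
    n_retained: int
    removed_low_ids: frozenset
    removed_high_ids: frozenset

    @property
    def removed_ids(self) -> frozenset:
        return self.removed_low_ids | self.removed_high_ids

    def __post_init__(self):
        if self.removed_low_ids & self.removed_high_ids:
            raise ValueError("a CpG cannot be flagged both low and high")
        if self.n_input != self.n_removed_low + self.n_removed_high + self.n_retained:
            raise ValueError("filter report counts are inconsistent")


def variance_filter(
    m: BetaMatrix,
    low: float = 0.05,
    high: float = 0.95,
    cohorts=None,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove CpGs consistently below ``low`` or above ``high``.

    ``cohorts`` optionally gives one group label per sample; a CpG is
    flagged if ALL its values within any single group fall below ``low``
    (or all above ``high``), and flagged CpGs are removed for every
    group. With ``cohorts=None`` the whole matrix is one group.
    Missing values are ignored when evaluating consistency.
    """
    if low >= high:
        raise ValueError(f"low threshold {low} must be smaller than high {high}")
    values = m.values
    if cohorts is None:
        groups = [np.ones(m.n_samples, dtype=bool)]
    else:
        cohorts = np.asarray(cohorts)
        if cohorts.shape[0] != m.n_samples:
            raise ValueError("cohort grouping length does not match sample count")
        groups = [cohorts == g for g in np.unique(cohorts)]

    low_flag = np.zeros(m.n_cpgs, dtype=bool)
    high_flag = np.zeros(m.n_cpgs, dtype=bool)
    for mask in groups:
        sub = values[mask]
        with np.errstate(invalid="ignore"):
            all_low = np.nanmax(np.where(np.isnan(sub), -np.inf, sub), axis=0) < low
            all_high = np.nanmin(np.where(np.isnan(sub), np.inf, sub), axis=0) > high
        low_flag |= all_low
        high_flag |= all_high
    # a CpG low in one group and high in another counts once, as low
    high_flag &= ~low_flag

    keep = ~(low_flag | high_flag)
    cpg_arr = np.asarray(m.cpg_ids, dtype=object)
    filtered = BetaMatrix(
        m.sample_ids, tuple(cpg_arr[keep].tolist()), values[:, keep]
    )
    report = FilterReport(
        n_input=m.n_cpgs,
        n_removed_low=int(low_flag.sum()),
        n_removed_high=int(high_flag.sum()),
        n_retained=int(keep.sum()),
        removed_low_ids=frozenset(cpg_arr[low_flag].tolist()),
        removed_high_ids=frozenset(cpg_arr[high_flag].tolist()),
    )
    return filtered, report


def intersect_cohorts(a: BetaMatrix, b: BetaMatrix):
    """Restrict two cohorts to their shared CpG panel, same column order.

    Returns ``(a_shared, b_shared, report)`` with ``report`` holding the
    counts dropped from each input. Raises if the panels are disjoint.
    """
    shared = [g for g in a.cpg_ids if g in set(b.cpg_ids)]
    if not shared:
        raise ValueError("cohort CpG panels are disjoint; nothing to analyse")
    report = {
        "n_shared": len(shared),
        "n_dropped_a": a.n_cpgs - len(shared),
        "n_dropped_b": b.n_cpgs - len(shared),
    }
    return a.select_cpgs(shared), b.select_cpgs(shared), report
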