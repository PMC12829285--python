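"""Pairwise differential methylation with moderated t statistics.

Each unordered pair of phenotype clusters is tested CpG-by-CpG with a
two-sample t statistic whose residual variance is shrunk towards a
common prior by empirical Bayes: the per-CpG variances s_g^2 (d_g
residual degrees of freedom each) are modelled as scaled F draws around
a prior (d0, s0^2) estimated from the marginal distribution of
log s_g^2 by moment matching — the mean and variance of
log s_g^2 - digamma(d_g/2) + log(d_g/2) identify d0 through a trigamma
inversion and s0^2 through the mean. The moderated statistic

    t_g = (mean1 - mean2) / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom.
p values are Benjamini-Hochberg adjusted within each contrast, and the
union of CpGs significant in any contrast feeds feature selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = ["moderated_t_contrast", "bh_adjust", "dmp_union", "trigamma_inverse"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved.

    ``adj_p[(i)] = min_{j >= i} min(1, p[(j)] * m / j)`` over the sorted
    p values, mapped back to the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Returns ``inf`` for x <= 0 (no finite solution: trigamma is positive
    and decreasing).
    """
    if not np.isfinite(x) or x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x  # good starting value for the decreasing branch
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < tol * max(y, 1.0):
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-feature sample variances.

    Moment matching on z = log(s2): under the scaled-F model,
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) + log(d0/2) - digamma(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2). Zero variances are
    excluded from estimation (they cannot arise from a continuous
    model and would send log s2 to -inf).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise FloatingPointError("too few positive variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    # unbiased sample variance of e minus the known df-part of Var[z]
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_contrast(
    m: BetaMatrix, labels, pair, prior: str = "eb"
) -> pd.DataFrame:
    """Moderated (or ordinary pooled) t test of one cluster pair.

    Returns one row per CpG with columns cpg_id, contrast, delta_beta,
    t_stat, df_total, p_value, adj_p. ``pair`` is ordered: delta_beta is
    mean(first) - mean(second). With ``prior="none"`` the ordinary
    pooled two-sample t is used and zero-variance CpGs are flagged with
    undefined (NaN) statistics.
    """
    if prior not in ("eb", "none"):
        raise ValueError(f"unknown prior: {prior!r}")
    labels = np.asarray(labels)
    g1, g2 = pair
    mask1 = labels == g1
    mask2 = labels == g2
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both clusters need >= 2 samples (got {n1}, {n2})")

    x1 = m.values[mask1]
    x2 = m.values[mask2]
    mean1 = x1.mean(axis=0)
    mean2 = x2.mean(axis=0)
    delta = mean1 - mean2
    ss = ((x1 - mean1) ** 2).sum(axis=0) + ((x2 - mean2) ** 2).sum(axis=0)
    df_res = n1 + n2 - 2
    s2 = ss / df_res
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    flagged = np.zeros(m.n_cpgs, dtype=bool)
    if prior == "eb":
        try:
            d0, s0_2 = _fit_variance_prior(s2, df_res)
        except FloatingPointError as err:
            logger.warning("EB prior estimation failed (%s); using prior='none'", err)
            d0, s0_2 = 0.0, 0.0
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
            df_total = d0 + df_res
    else:
        s2_tilde = s2
        df_total = float(df_res)
        flagged = s2 == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_tilde) * se_factor)
    t = np.where((delta == 0) & ~np.isfinite(t), 0.0, t)
    # zero residual variance with a nonzero difference: t undefined
    t = np.where(~np.isfinite(t), np.nan, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), np.nan, p)
    flagged |= np.isnan(t)

    valid = ~np.isnan(p)
    adj = np.full(m.n_cpgs, np.nan)
    if valid.any():
        adj[valid] = bh_adjust(p[valid])

    return pd.DataFrame(
        {
            "cpg_id": list(m.cpg_ids),
            "contrast": f"{g1}_vs_{g2}",
            "delta_beta": delta,
            "t_stat": t,
            "df_total": df_total,
            "p_value": p,
            "adj_p": adj,
            "flagged": flagged,
        }
    )


def dmp_union(
    m: BetaMatrix, labels, fdr: float = 0.05, prior: str = "eb"
) -> tuple[set, pd.DataFrame]:
    """All pairwise contrasts; union of CpGs significant in any of them.

    BH adjustment is applied within each contrast separately (each
    pairwise comparison is its own testing family). Returns the set of
    CpGs with adj_p < ``fdr`` in at least one contrast, plus the full
    record table (one row per CpG x contrast).
    """
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for pairwise contrasts")
    tables = [
        moderated_t_contrast(m, labels, pair, prior=prior)
        for pair in itertools.combinations(clusters, 2)
    ]
    records = pd.concat(tables, ignore_index=True)
    sig = records.loc[records["adj_p"] < fdr, "cpg_id"]
    return set(sig), records
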