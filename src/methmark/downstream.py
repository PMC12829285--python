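"""Downstream characterisation of the consensus CpG markers.

Four independent surfaces:

* a Spearman screen of every consensus CpG against every clinical /
  anthropometric trait, with significance on the raw p value (the
  screen is descriptive; no multiplicity adjustment, by design);
* cluster-specificity assignment from per-class elastic-net selection
  frequencies (singleton membership = cluster-specific; multiple
  memberships = mixed, the Venn-diagram surface);
* hyper/hypomethylation direction calls for cluster-specific CpGs
  (target-cluster mean vs the pooled mean of all other samples);
* CpG -> gene annotation (promoter = within 2 kb of a TSS, gene body =
  within the first-to-last-exon span, else intergenic) and overlap
  counts against an external CpG-trait association catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix
from .selection import ConsensusSet

__all__ = [
    "spearman_screen",
    "assign_specificity",
    "direction_call",
    "annotate_cpgs",
    "catalogue_overlap",
    "SpecificityRecord",
]

PROMOTER_WINDOW = 2000  # bp either side of the TSS


def spearman_screen(
    m: BetaMatrix, traits: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation of every CpG against every trait column.

    ``traits`` is indexed by sample id (or carries a ``sample_id``
    column) with one numeric column per trait. Rank correlation uses
    average ranks (tie-corrected); p values come from the t
    approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees
    of freedom, with ``|rho| = 1`` mapped to p = 0. Pairs with fewer
    than 4 complete observations, or a constant CpG or trait, are
    flagged and excluded from the per-trait significant counts.

    Returns the record table and a per-trait Series of significant
    counts (raw p < alpha).
    """
    if "sample_id" in traits.columns:
        traits = traits.set_index("sample_id")
    traits = traits.loc[list(m.sample_ids)]
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        for j, g in enumerate(m.cpg_ids):
            x = m.values[:, j]
            mask = ok & ~np.isnan(x)
            n = int(mask.sum())
            flagged = False
            rho = p = np.nan
            if n < 4:
                flagged = True
            else:
                xr = stats.rankdata(x[mask])
                yr = stats.rankdata(y[mask])
                if np.ptp(xr) == 0 or np.ptp(yr) == 0:
                    flagged = True
                else:
                    rho = float(np.corrcoef(xr, yr)[0, 1])
                    if abs(rho) >= 1.0 - 1e-12:
                        p = 0.0
                    else:
                        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
                        p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append(
                {
                    "cpg_id": g,
                    "trait": trait,
                    "rho": rho,
                    "p_value": p,
                    "n": n,
                    "significant": bool(p < alpha) if not flagged else False,
                    "flagged": flagged,
                }
            )
    records = pd.DataFrame(rows)
    counts = (
        records[~records["flagged"]]
        .groupby("trait")["significant"]
        .sum()
        .astype(int)
    )
    return records, counts


@dataclass(frozen=True)
class SpecificityRecord:
    cpg_id: str
    class_sets: frozenset  # clusters whose per-class frequency clears threshold
    specific_to: int | None
    weak: bool = False  # no class cleared threshold; argmax fallback


def assign_specificity(
    consensus: ConsensusSet, threshold: float = 0.10
) -> tuple[list[SpecificityRecord], dict]:
    """Cluster membership of each retained CpG from per-class frequencies.

    A CpG belongs to every cluster whose per-class selection frequency
    reaches ``threshold``; a singleton membership makes it
    cluster-specific. CpGs clearing the overall threshold but no single
    class keep their argmax class and are flagged weak. Returns the
    records plus Venn region counts keyed by frozenset of clusters.
    """
    clusters = sorted(consensus.frequencies_per_class)
    records = []
    venn: dict = {}
    for g in sorted(consensus.retained):
        freqs = {
            c: consensus.frequencies_per_class.get(c, {}).get(g, 0.0) for c in clusters
        }
        members = frozenset(c for c, f in freqs.items() if f >= threshold)
        weak = False
        if not members:
            best = max(clusters, key=lambda c: (freqs[c], -c))
            members = frozenset([best])
            weak = True
        specific = next(iter(members)) if len(members) == 1 else None
        records.append(SpecificityRecord(g, members, specific, weak))
        venn[members] = venn.get(members, 0) + 1
    return records, venn


def direction_call(m: BetaMatrix, labels, record: SpecificityRecord) -> str:
    """hyper/hypo call for a cluster-specific CpG (target vs pooled rest)."""
    if record.specific_to is None:
        raise ValueError(f"{record.cpg_id} is not cluster-specific")
    labels = np.asarray(labels)
    if record.specific_to not in set(labels.tolist()):
        raise ValueError(f"cluster {record.specific_to} absent from labels")
    j = m.cpg_ids.index(record.cpg_id)
    x = m.values[:, j]
    in_c = labels == record.specific_to
    mean_target = float(np.nanmean(x[in_c]))
    mean_rest = float(np.nanmean(x[~in_c]))
    if mean_target > mean_rest:
        return "hyper"
    if mean_target < mean_rest:
        return "hypo"
    return "indeterminate"


def annotate_cpgs(
    cpg_positions: pd.DataFrame, gene_table: pd.DataFrame
) -> pd.DataFrame:
    """Assign each CpG a region label and (where applicable) a gene.

    ``cpg_positions`` needs columns cpg_id, chrom, pos (0-based);
    ``gene_table`` columns gene, chrom, tss, first_exon_start,
    last_exon_end (0-based, half-open exon span). Promoter (within
    ``PROMOTER_WINDOW`` bp of the nearest TSS on the same chromosome)
    takes precedence over gene body; a CpG inside some gene's exon span
    is gene_body; everything else is intergenic with no gene assigned.
    Nearest-gene ties go to the alphabetically first gene. CpGs on
    chromosomes absent from the gene table are flagged unmapped.
    """
    required = {"cpg_id", "chrom", "pos"}
    if not required <= set(cpg_positions.columns):
        raise ValueError(f"cpg_positions requires columns {sorted(required)}")
    by_chrom = {c: t.reset_index(drop=True) for c, t in gene_table.groupby("chrom")}
    rows = []
    for rec in cpg_positions.itertuples(index=False):
        genes = by_chrom.get(rec.chrom)
        if genes is None:
            rows.append(
                {
                    "cpg_id": rec.cpg_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "gene": None,
                    "region": "unmapped",
                }
            )
            continue
        dist = (genes["tss"] - rec.pos).abs()
        order = sorted(range(len(genes)), key=lambda i: (dist.iloc[i], genes["gene"].iloc[i]))
        nearest = order[0]
        gene = None
        if dist.iloc[nearest] <= PROMOTER_WINDOW:
            region = "promoter"
            gene = genes["gene"].iloc[nearest]
        else:
            inside = genes[
                (genes["first_exon_start"] <= rec.pos)
                & (rec.pos < genes["last_exon_end"])
            ]
            if len(inside):
                region = "gene_body"
                gene = sorted(inside["gene"])[0]
            else:
                region = "intergenic"
        rows.append(
            {
                "cpg_id": rec.cpg_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "gene": gene,
                "region": region,
            }
        )
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos", "gene", "region"])


def catalogue_overlap(
    cpgs, catalogue: pd.DataFrame, specificity=None
) -> pd.DataFrame:
    """Overlap counts between a CpG set and a CpG-trait catalogue.

    Returns one row per trait category with the number of input CpGs the
    catalogue lists under it (a CpG listed under several categories
    counts once in each). With ``specificity`` (SpecificityRecord
    collection) the counts are additionally broken down per
    cluster-specific set plus a mixed-membership column.
    """
    cpgs = set(cpgs)
    cats = sorted(set(catalogue["trait_category"]))
    listed = {
        cat: set(catalogue.loc[catalogue["trait_category"] == cat, "cpg_id"])
        for cat in cats
    }
    rows = []
    spec_groups = None
    if specificity is not None:
        spec_groups = {}
        for rec in specificity:
            key = rec.specific_to if rec.specific_to is not None else "mixed"
            spec_groups.setdefault(key, set()).add(rec.cpg_id)
    for cat in cats:
        row = {"trait_category": cat, "n_overlap": len(cpgs & listed[cat])}
        if spec_groups is not None:
            for key, members in sorted(spec_groups.items(), key=lambda kv: str(kv[0])):
                row[f"n_overlap_{key}"] = len(members & listed[cat])
        rows.append(row)
    return pd.DataFrame(rows)
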