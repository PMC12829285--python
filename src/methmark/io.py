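"""Readers and writers for beta matrices, sample sheets and annotation tables.

On-disk convention: delimited text (TSV by default) with a header row
and identifiers in the first column. Beta matrices are stored samples x
CpGs; a CpGs x samples file can be read with ``orientation="cpgs_by_samples"``
and is transposed on load. Missing beta values are the literal ``NA`` /
empty cell and become NaN in memory — never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_table",
    "read_catalogue",
    "DISCOVERY_CLUSTERS",
    "REPLICATION_CLUSTERS",
]

#: Phenotype risk-cluster labels: 2 = low risk, 3 = low beta-cell
#: function, 5 = insulin resistance / fatty liver, 6 = high insulin
#: secretion / visceral fat. The replication design contains only the
#: three high-risk clusters.
DISCOVERY_CLUSTERS = (2, 3, 5, 6)
REPLICATION_CLUSTERS = (3, 5, 6)

_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class BetaMatrix:
    """A samples x CpGs matrix of methylation beta values in [0, 1].

    ``values`` carries float64 data; NaN marks a missing measurement.
    Identifiers are unique along both axes.
    """

    sample_ids: tuple
    cpg_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        if values.ndim != 2:
            raise ValueError("beta matrix must be two-dimensional")
        if values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.sample_ids)} samples "
                f"x {len(self.cpg_ids)} CpGs"
            )
        for axis, ids in (("sample", self.sample_ids), ("CpG", self.cpg_ids)):
            if len(set(ids)) != len(ids):
                seen, dups = set(), set()
                for i in ids:
                    (dups if i in seen else seen).add(i)
                raise ValueError(f"duplicated {axis} identifiers: {sorted(dups)[:5]}")
        finite = values[~np.isnan(values)]
        if finite.size and (np.isinf(finite).any()):
            raise ValueError("beta matrix contains non-finite values")
        if finite.size and (
            finite.min() < -_BOUND_TOL or finite.max() > 1.0 + _BOUND_TOL
        ):
            bad = finite[(finite < -_BOUND_TOL) | (finite > 1.0 + _BOUND_TOL)]
            raise ValueError(
                f"beta values outside [0, 1]: e.g. {bad.flat[0]!r} "
                f"({bad.size} offending entries)"
            )

    # -- basic container behaviour ------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.cpg_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))

    def select_cpgs(self, cpg_ids) -> "BetaMatrix":
        """Restrict to the given CpGs, in the given order."""
        pos = {g: i for i, g in enumerate(self.cpg_ids)}
        missing = [g for g in cpg_ids if g not in pos]
        if missing:
            raise KeyError(f"unknown CpG identifiers: {missing[:5]}")
        idx = [pos[g] for g in cpg_ids]
        return BetaMatrix(self.sample_ids, tuple(cpg_ids), self.values[:, idx])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return BetaMatrix(tuple(sample_ids), self.cpg_ids, self.values[idx, :])

    def drop_missing_cpgs(self) -> "BetaMatrix":
        """Drop any CpG with at least one missing value (logged count)."""
        keep = ~np.isnan(self.values).any(axis=0)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d CpGs with missing values", n_drop)
        return BetaMatrix(
            self.sample_ids,
            tuple(g for g, k in zip(self.cpg_ids, keep) if k),
            self.values[:, keep],
        )


def read_beta_matrix(path, orientation: str = "samples_by_cpgs", sep: str = "\t") -> BetaMatrix:
    """Read a beta matrix from delimited text.

    Returns a samples x CpGs matrix regardless of on-disk orientation.
    Non-numeric cells and out-of-range values raise with the offending
    row/column named.
    """
    if orientation not in ("samples_by_cpgs", "cpgs_by_samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "NaN", ""])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric cell at row {bad[0]!r}, column {col!r} in {path}"
            )
    if orientation == "cpgs_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix.from_frame(df)


def write_beta_matrix(m: BetaMatrix, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


REQUIRED_SHEET_COLUMNS = ("sample_id", "cohort", "cluster")
_COHORT_CLUSTERS = {
    "discovery": set(DISCOVERY_CLUSTERS),
    "replication": set(REPLICATION_CLUSTERS),
}


def read_sample_sheet(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a sample sheet.

    Required columns: ``sample_id``, ``cohort`` (discovery/replication)
    and ``cluster`` (2, 3, 5 or 6; replication restricted to 3/5/6).
    Any further numeric columns are preserved as traits; ``age`` and
    ``sex`` are ordinary columns.
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet is missing required columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample identifiers: {dups[:5]}")
    bad_cohort = set(df["cohort"]) - set(_COHORT_CLUSTERS)
    if bad_cohort:
        raise ValueError(f"unknown cohort labels: {sorted(bad_cohort)}")
    df["cluster"] = df["cluster"].astype(int)
    for cohort, allowed in _COHORT_CLUSTERS.items():
        found = set(df.loc[df["cohort"] == cohort, "cluster"])
        if not found <= allowed:
            raise ValueError(
                f"cluster labels {sorted(found - allowed)} not allowed in the "
                f"{cohort} cohort (allowed: {sorted(allowed)})"
            )
    return df


def write_sample_sheet(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def trait_columns(sheet: pd.DataFrame) -> list[str]:
    """Numeric columns of a sample sheet other than the schema columns."""
    reserved = set(REQUIRED_SHEET_COLUMNS) | {"age", "sex"}
    return [
        c
        for c in sheet.columns
        if c not in reserved and pd.api.types.is_numeric_dtype(sheet[c])
    ]


def cluster_labels(sheet: pd.DataFrame, sample_ids) -> np.ndarray:
    """Phenotype cluster labels aligned to the given sample order."""
    lut = sheet.set_index("sample_id")["cluster"]
    missing = [s for s in sample_ids if s not in lut.index]
    if missing:
        raise KeyError(f"samples absent from sheet: {missing[:5]}")
    return lut.loc[list(sample_ids)].to_numpy(dtype=int)


GENE_TABLE_COLUMNS = ("gene", "chrom", "tss", "first_exon_start", "last_exon_end")


def read_gene_table(path, sep: str = "\t", one_based: bool = False) -> pd.DataFrame:
    """Read a BED-like gene table (0-based, half-open coordinates).

    Columns: gene, chrom, tss, first_exon_start, last_exon_end. Set
    ``one_based=True`` for 1-based input; coordinates are shifted down
    by one on read.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table is missing columns: {missing}")
    df = df.copy()
    for col in ("tss", "first_exon_start", "last_exon_end"):
        df[col] = df[col].astype(int)
        if one_based:
            df[col] -= 1
    return df


def read_catalogue(path, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column CpG/trait association catalogue."""
    df = pd.read_csv(path, sep=sep)
    if not {"cpg_id", "trait_category"} <= set(df.columns):
        raise ValueError("catalogue requires columns cpg_id, trait_category")
    return df
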