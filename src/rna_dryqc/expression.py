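"""Gene-level counting, FPKM, expression filters and group comparison.

Counting is union-exon and gene-level: a read belongs to a gene iff any
alignment block overlaps the gene's merged exons; reads touching exons of
more than one gene are discarded as ambiguous.  FPKM is computed against the
per-sample total of *assigned* reads M:

    FPKM_g = count_g * 1e9 / (L_g * M)

with L_g the meta-transcript (union exon) length in nt, which gives the exact
per-sample identity  sum_g FPKM_g * L_g/1000 = 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AMBIGUOUS, POLYA_FREE_BIOTYPES

logger = logging.getLogger(__name__)


def count_reads(assignments: pd.DataFrame, gene_ids, include_duplicates: bool = True) -> tuple[pd.Series, int, int]:
    """Per-gene read counts for one sample.

    Returns (counts over all gene_ids, n_ambiguous, n_unassigned).
    Duplicate-flagged reads are included by default (counting happens on all
    mapped reads; duplicate marking is informational).
    """
    df = assignments if include_duplicates else assignments[~assignments["duplicate"]]
    ambiguous = int((df["gene_id"] == AMBIGUOUS).sum())
    unassigned = int(df["gene_id"].isna().sum())
    assigned = df[df["gene_id"].notna() & (df["gene_id"] != AMBIGUOUS)]
    counts = assigned["gene_id"].value_counts()
    return counts.reindex(gene_ids, fill_value=0).astype(int), ambiguous, unassigned


def counts_matrix(assignments_by_sample: dict[str, pd.DataFrame], gene_ids, include_duplicates: bool = True) -> pd.DataFrame:
    """Gene x sample count matrix from per-sample assignment tables."""
    cols = {}
    for sample, df in assignments_by_sample.items():
        cols[sample], _, _ = count_reads(df, gene_ids, include_duplicates)
    return pd.DataFrame(cols)


def fpkm(counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM matrix: count * 1e9 / (L * M), M = per-sample assigned total."""
    L = lengths.reindex(counts.index)
    if L.isna().any() or (L <= 0).any():
        bad = L.index[L.isna() | (L <= 0)][:5].tolist()
        raise ValueError(f"missing/non-positive meta-transcript length for genes {bad}")
    M = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (M <= 0).any():
        raise ValueError("library size M is zero for at least one sample")
    return counts * 1.0e9 / np.outer(L.to_numpy(dtype=float), M.to_numpy(dtype=float))


def filter_expressed(fpkm_table: pd.DataFrame, biotypes: pd.Series, min_fpkm: float = 1.0) -> pd.DataFrame:
    """The expression filter: drop never-expressed genes and poly(A)-free RNAs.

    A gene is kept iff FPKM >= min_fpkm in at least one sample (the boundary
    value is retained: "below 1 across all samples" is discarded) and its
    biotype is not a poly(A)-free small-RNA class.
    """
    expressed = (fpkm_table >= min_fpkm).any(axis=1)
    polya_ok = ~biotypes.reindex(fpkm_table.index).isin(POLYA_FREE_BIOTYPES)
    return fpkm_table[expressed & polya_ok]


def abundance_class(value: float) -> str:
    """Expression stratum by FPKM: high >100, moderate 10-100, low 1-10, else extremely_low."""
    if value > 100:
        return "high"
    if value >= 10:
        return "moderate"
    if value >= 1:
        return "low"
    return "extremely_low"


@dataclass
class ComparisonSummary:
    group_means: pd.DataFrame  # genes x {control, treated}
    r_squared: float
    folds: pd.Series  # control mean / treated mean for the DE genes
    fold_median: float | None
    fold_range: tuple[float, float] | None
    abundance: pd.Series = field(default=None)  # type: ignore[assignment]
    skipped_de_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "n_genes": int(len(self.group_means)),
            "n_de": int(len(self.folds)),
            "fold_median": self.fold_median,
            "fold_range": list(self.fold_range) if self.fold_range else None,
            "folds": {g: float(v) for g, v in self.folds.items()},
            "skipped_de_genes": self.skipped_de_genes,
        }


def group_comparison(
    fpkm_table: pd.DataFrame,
    groups: dict[str, str],
    control: str,
    treated: str,
    de_genes=None,
) -> ComparisonSummary:
    """Group-mean FPKMs, log2 scatter R^2 and per-DE-gene folds.

    Fold is oriented control/treated, so genes downsampled in the treated
    group have fold > 1.  R^2 is the squared Pearson correlation of log2 group
    means over genes with both means > 0.  DE genes absent from the (filtered)
    table are skipped with a warning.
    """
    ctrl_samples = [s for s in fpkm_table.columns if groups[s] == control]
    trt_samples = [s for s in fpkm_table.columns if groups[s] == treated]
    if len(ctrl_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("need >=2 samples per group for a group comparison")
    means = pd.DataFrame(
        {control: fpkm_table[ctrl_samples].mean(axis=1), treated: fpkm_table[trt_samples].mean(axis=1)}
    )
    both = means[(means[control] > 0) & (means[treated] > 0)]
    if len(both) >= 2:
        r = np.corrcoef(np.log2(both[control]), np.log2(both[treated]))[0, 1]
        r2 = float(r * r)
    else:
        r2 = float("nan")
    skipped: list[str] = []
    if de_genes is None:
        de_present: list[str] = []
    else:
        de_present = [g for g in de_genes if g in means.index]
        skipped = [g for g in de_genes if g not in means.index]
        for g in skipped:
            logger.warning("DE gene %s absent from the filtered expression table; skipped", g)
    folds = pd.Series(dtype=float)
    if de_present:
        sub = means.loc[de_present]
        folds = sub[control] / sub[treated]
    fold_median = float(folds.median()) if len(folds) else None
    fold_range = (float(folds.min()), float(folds.max())) if len(folds) else None
    abundance = means[control].map(abundance_class)
    return ComparisonSummary(
        group_means=means,
        r_squared=r2,
        folds=folds,
        fold_median=fold_median,
        fold_range=fold_range,
        abundance=abundance,
        skipped_de_genes=skipped,
    )
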