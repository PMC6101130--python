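"""Gene-body coverage profiles (40 x 2.5% bins) and cumulative gene diversity.

Coverage bins a read by the meta-position of its 5' end only: bin
floor(40*m/L) with bin 1 at the 5' end.  Under poly(A) capture, 5'-ward
degradation empties the low bins, so a 3'-skewed profile is the degradation
signature.  Cumulative gene diversity is the fraction of assigned reads
captured by the top-k most abundant genes (k = 10, 100, 1000, 10000): a shift
toward the head of the curve means a low-complexity library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 40
DIVERSITY_RANKS = (10, 100, 1000, 10000)


def select_upper_middle_quartile(counts: pd.Series) -> set[str]:
    """Genes whose read count lies in [P50, P75) of expressed-gene counts.

    Percentiles use linear interpolation on the sorted counts over expressed
    genes (count > 0).  If P50 == P75 (massive ties), the tied genes at that
    value are selected.  Fewer than 4 expressed genes is an error.
    """
    expressed = counts[counts > 0]
    if len(expressed) < 4:
        raise ValueError(f"need >=4 expressed genes to form quartiles, got {len(expressed)}")
    p50, p75 = np.percentile(expressed.to_numpy(dtype=float), [50, 75])
    if p50 == p75:
        sel = expressed[expressed == p50]
    else:
        sel = expressed[(expressed >= p50) & (expressed < p75)]
    return set(sel.index)


@dataclass
class CoverageProfile:
    sample_id: str
    fractions: np.ndarray  # length 40; bin 1 (index 0) = 5' end
    n_genes: int
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "bin": np.arange(1, N_BINS + 1),
                "fraction": self.fractions,
            }
        )


def gene_body_coverage(assignments: pd.DataFrame, metas, gene_set, sample_id: str = "") -> CoverageProfile:
    """Aggregate 5'-end bin fractions over the genes in ``gene_set``.

    ``assignments`` is the per-read table from GenomeIndex.assign_reads (one
    sample).  Genes shorter than 40 nt cannot populate 40 distinct bins and
    are excluded with a log message.
    """
    if not gene_set:
        raise ValueError("gene set for coverage profiling is empty")
    usable = {g for g in gene_set if metas[g].length >= N_BINS}
    skipped = set(gene_set) - usable
    if skipped:
        logger.info("coverage: excluded %d genes shorter than %d nt", len(skipped), N_BINS)
    sub = assignments[assignments["gene_id"].isin(usable) & (assignments["meta_pos"] >= 0)]
    if len(sub) == 0:
        raise ValueError("no reads fall in the selected gene set")
    lengths = sub["gene_id"].map({g: metas[g].length for g in usable}).to_numpy(dtype=float)
    m = sub["meta_pos"].to_numpy(dtype=float)
    bins = np.floor(N_BINS * m / lengths).astype(int)
    bins = np.clip(bins, 0, N_BINS - 1)
    hist = np.bincount(bins, minlength=N_BINS).astype(float)
    return CoverageProfile(
        sample_id=sample_id,
        fractions=hist / hist.sum(),
        n_genes=int(sub["gene_id"].nunique()),
        n_reads=int(len(sub)),
    )


@dataclass
class DiversityCurve:
    sample_id: str
    fractions: dict[int, float]  # rank -> cumulative read fraction
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "rank": list(self.fractions),
                "fraction": list(self.fractions.values()),
            }
        )


def cumulative_gene_diversity(counts: pd.Series, ranks=DIVERSITY_RANKS, sample_id: str = "") -> DiversityCurve:
    """Fraction of assigned reads on the top-k genes for each rank k.

    Genes are sorted by descending count with ties broken by gene_id so the
    curve is deterministic.  If fewer than k genes exist the fraction is 1.
    """
    if (counts < 0).any():
        raise ValueError("negative read counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all gene counts are zero")
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable").to_numpy(dtype=float)
    cum = np.cumsum(ordered)
    fractions = {int(k): float(cum[min(int(k), len(cum)) - 1] / total) for k in ranks}
    return DiversityCurve(sample_id=sample_id, fractions=fractions, total_reads=int(total))
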