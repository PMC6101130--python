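"""Transcript-feature comparisons (Mann-Whitney) and ARE/bias overlap counts.

The feature comparison asks whether differentially affected genes differ from
the annotation background in transcript length and %GC (lncRNA stratum) or in
cDNA/CDS/UTR lengths and %GC (protein-coding stratum).  The overlap counter
partitions the DE set by AU-rich-element (ARE) annotation and by the
degradation-bias class, the two candidate decay routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bias import FIVE_PRIME, THREE_PRIME

logger = logging.getLogger(__name__)

EXACT_MAX_PRODUCT = 400

#: Features compared per biotype stratum (column names of the feature table).
STRATUM_FEATURES = {
    "lncRNA": ("transcript_length", "transcript_gc", "transcript_gc_pct"),
    "protein_coding": (
        "cdna_length",
        "cdna_gc_pct",
        "cds_length",
        "cds_gc_pct",
        "utr5_length",
        "utr5_gc_pct",
        "utr3_length",
        "utr3_gc_pct",
    ),
}


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U for group A, P).

    Uses the exact null distribution when n1*n2 <= 400 and the data are
    tie-free; otherwise the normal approximation with midranks, tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires non-empty groups")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= EXACT_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FeatureComparison:
    stratum: str
    feature: str
    n_background: int
    n_de: int
    median_background: float
    median_de: float
    u_statistic: float
    p_value: float
    low_power: bool = False


def compare_features(
    de_genes,
    features: pd.DataFrame,
    strata: dict[str, tuple[str, ...]] | None = None,
    exclude_de_from_background: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney comparison of DE genes against the stratum background.

    The background is all annotated genes of the stratum, *including* the DE
    genes by default (the all-vs-DE convention; set
    ``exclude_de_from_background`` to drop them).  Genes with an absent
    feature (e.g. no 3'UTR) are excluded from that feature's vectors.  Strata
    with fewer than 3 DE genes are reported with a low-power flag, not
    suppressed.
    """
    strata = strata or STRATUM_FEATURES
    de_set = set(de_genes)
    rows = []
    for stratum, feats in strata.items():
        stratum_genes = features[features["biotype"] == stratum]
        de_sub = stratum_genes[stratum_genes.index.isin(de_set)]
        bg = stratum_genes.drop(index=de_sub.index) if exclude_de_from_background else stratum_genes
        low_power = len(de_sub) < 3
        if low_power:
            logger.warning("stratum %s: only %d DE genes; comparisons are low-powered", stratum, len(de_sub))
        if len(de_sub) == 0:
            continue
        for feat in feats:
            if feat not in features.columns:
                continue
            a = de_sub[feat].dropna()
            b = bg[feat].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            u, p = mann_whitney(a, b)
            rows.append(
                FeatureComparison(
                    stratum=stratum,
                    feature=feat,
                    n_background=len(b),
                    n_de=len(a),
                    median_background=float(b.median()),
                    median_de=float(a.median()),
                    u_statistic=u,
                    p_value=p,
                    low_power=low_power,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class OverlapCounts:
    both: int
    are_only: int
    bias_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.are_only + self.bias_only + self.neither

    def to_dict(self) -> dict:
        return {"both": self.both, "are_only": self.are_only, "bias_only": self.bias_only, "neither": self.neither}


def are_overlap(de_genes, are_table: pd.DataFrame, bias_table: pd.DataFrame) -> OverlapCounts:
    """Four-way partition of the DE set by ARE annotation and bias class.

    A gene has an ARE iff its 3'UTR or intron flag is set (both sources
    count); it has bias iff classified 5'- or 3'-underrepresented.  Genes
    missing from the ARE table are treated as ARE-free (logged).
    """
    are = are_table.set_index("gene_id") if "gene_id" in are_table.columns else are_table
    both = are_only = bias_only = neither = 0
    for g in de_genes:
        if g in are.index:
            row = are.loc[g]
            has_are = bool(row.get("are_3utr", False)) or bool(row.get("are_intron", False))
        else:
            logger.info("gene %s missing from ARE table; treated as ARE-free", g)
            has_are = False
        has_bias = g in bias_table.index and bias_table.loc[g, "bias_class"] in (FIVE_PRIME, THREE_PRIME)
        if has_are and has_bias:
            both += 1
        elif has_are:
            are_only += 1
        elif has_bias:
            bias_only += 1
        else:
            neither += 1
    return OverlapCounts(both, are_only, bias_only, neither)
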