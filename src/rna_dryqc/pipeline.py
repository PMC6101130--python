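"""End-to-end orchestration: annotation -> QC -> coverage/diversity ->
expression -> bias -> enrichment (-> qPCR), with one JSON summary.

Every stage writes its own TSV/JSON under the output directory; re-running
with identical inputs and config produces byte-identical files (all
randomness is seeded upstream in the simulator; the pipeline itself is
deterministic).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import bias as bias_mod
from . import coverage as cov_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import qc as qc_mod
from . import qpcr as qpcr_mod
from .annotation import GenomeIndex, feature_table, read_gtf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and stage toggles for one pipeline run."""

    gtf: str
    fasta: str
    sam: dict[str, str]  # sample_id -> SAM path
    groups: dict[str, str]  # sample_id -> group label
    control: str = "control"
    treated: str = "lyo"
    outdir: str = "rna_dryqc_out"
    de_list: str | None = None
    are_table: str | None = None
    cp_table: str | None = None
    qpcr_reference: str = "ACTB"
    qpcr_integrity: tuple[str, str] | None = None  # (5' assay, 3' assay)
    alpha_bias: float = 0.01
    fdr_mismatch: float = 0.05
    min_fpkm: float = 1.0
    outlier_threshold: float = 0.30
    mapq_threshold: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gtf", "fasta"):
            if not getattr(self, name):
                raise ValueError(f"config missing required field: {name}")
        if not self.sam:
            raise ValueError("config missing required field: sam")
        missing = set(self.sam) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        for thr in (self.alpha_bias, self.fdr_mismatch):
            if not 0 < thr < 1:
                raise ValueError(f"threshold {thr} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "qpcr_integrity" in raw and raw["qpcr_integrity"] is not None:
            raw["qpcr_integrity"] = tuple(raw["qpcr_integrity"])
        return cls(**raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "samples": sorted(config.sam), "groups": config.groups}

    # --- annotation ---
    genes = read_gtf(config.gtf)
    fasta = Fasta(config.fasta)
    index = GenomeIndex(genes)
    features = feature_table(genes, fasta)
    features.to_csv(out / "features.tsv", sep="\t")

    # --- per-sample SAM -> reads, metrics, mismatch profiles, assignments ---
    metrics_rows = {}
    profiles: dict[str, qc_mod.MismatchProfile] = {}
    assignments: dict[str, pd.DataFrame] = {}
    gene_ids = [g.gene_id for g in genes]
    for sample in sorted(config.sam):
        reads, totals = qc_mod.read_sam(config.sam[sample], mapq_threshold=config.mapq_threshold, fasta=fasta)
        assignments[sample] = index.assign_reads(reads)
        counts, _, _ = expr_mod.count_reads(assignments[sample], gene_ids)
        lm = qc_mod.library_metrics(
            reads, totals, sample_id=sample, group=config.groups[sample],
            detected_genes=int((counts > 0).sum()),
        )
        metrics_rows[sample] = lm
        profiles[sample] = qc_mod.mismatch_profile(reads, sample_id=sample)
        profiles[sample].to_frame().to_csv(out / f"mismatch_profile.{sample}.tsv", sep="\t", index=False)
    _dump_json({s: m.to_dict() for s, m in metrics_rows.items()}, out / "library_metrics.json")

    metric_df = pd.DataFrame(
        {
            s: {
                "unique_fraction": m.unique_fraction,
                "duplication_rate": m.duplication_rate,
                "detected_genes": m.detected_genes,
            }
            for s, m in metrics_rows.items()
        }
    ).T
    deviations, outliers = qc_mod.deviation_from_median(metric_df, threshold=config.outlier_threshold)
    deviations.assign(outlier=outliers).to_csv(out / "qc_deviations.tsv", sep="\t")
    summary["qc_outliers"] = sorted(outliers[outliers].index)

    ctrl = sorted(s for s in config.sam if config.groups[s] == config.control)
    trt = sorted(s for s in config.sam if config.groups[s] == config.treated)
    if len(ctrl) >= 2 and len(trt) >= 2:
        mm_cmp = qc_mod.compare_mismatch_profiles(
            [profiles[s] for s in ctrl], [profiles[s] for s in trt], fdr=config.fdr_mismatch
        )
        mm_cmp.to_csv(out / "mismatch_comparison.tsv", sep="\t", index=False)
        summary["mismatch_significant_cells"] = int(mm_cmp["significant"].sum())

    # --- biotype distribution ---
    biotype = {}
    for sample in sorted(config.sam):
        fractions, unassigned = qc_mod.biotype_distribution(assignments[sample], genes)
        biotype[sample] = {"fractions": fractions, "unassigned": unassigned}
    _dump_json(biotype, out / "biotype_distribution.json")

    # --- counts, coverage, diversity ---
    counts = expr_mod.counts_matrix(assignments, gene_ids)
    counts.to_csv(out / "counts.tsv", sep="\t")
    cov_frames, div_frames = [], []
    for sample in sorted(config.sam):
        umq = cov_mod.select_upper_middle_quartile(counts[sample])
        prof = cov_mod.gene_body_coverage(assignments[sample], index.metas, umq, sample_id=sample)
        cov_frames.append(prof.to_frame())
        div = cov_mod.cumulative_gene_diversity(counts[sample], sample_id=sample)
        div_frames.append(div.to_frame())
    pd.concat(cov_frames).to_csv(out / "gene_body_coverage.tsv", sep="\t", index=False)
    pd.concat(div_frames).to_csv(out / "gene_diversity.tsv", sep="\t", index=False)

    # --- expression ---
    lengths = pd.Series({g: index.metas[g].length for g in gene_ids}, dtype=float)
    biotypes = pd.Series({g.gene_id: g.biotype for g in genes})
    fpkm = expr_mod.fpkm(counts, lengths)
    fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    filtered = expr_mod.filter_expressed(fpkm, biotypes, min_fpkm=config.min_fpkm)
    de_genes = None
    if config.de_list:
        de_genes = [l.strip() for l in Path(config.de_list).read_text().splitlines() if l.strip()]
    cmp = expr_mod.group_comparison(filtered, config.groups, config.control, config.treated, de_genes=de_genes)
    _dump_json(cmp.to_dict(), out / "expression_comparison.json")
    summary["r_squared"] = cmp.r_squared
    summary["n_expressed_genes"] = int(len(filtered))

    # --- degradation bias (DE genes, else every filtered gene) ---
    bias_genes = [g for g in (de_genes or filtered.index.tolist()) if g in index.metas]
    bias_table, bias_bins = bias_mod.classify_genes(
        assignments, index.metas, bias_genes, config.groups, config.control, config.treated,
        alpha=config.alpha_bias,
    )
    bias_table.to_csv(out / "bias.tsv", sep="\t")
    bias_bins.to_csv(out / "bias_bins.tsv", sep="\t", index=False)
    summary["bias_classes"] = bias_table["bias_class"].value_counts().to_dict()

    # --- enrichment ---
    de_for_enrich = de_genes or bias_genes
    comp = enr_mod.compare_features(de_for_enrich, features)
    comp.to_csv(out / "feature_comparison.tsv", sep="\t", index=False)
    if config.are_table:
        are = pd.read_csv(config.are_table, sep="\t")
        overlap = enr_mod.are_overlap(de_for_enrich, are, bias_table)
        _dump_json(overlap.to_dict(), out / "are_overlap.json")
        summary["are_overlap"] = overlap.to_dict()

    # --- qPCR ---
    if config.cp_table:
        records = qpcr_mod.read_cp_table(config.cp_table)
        if config.qpcr_integrity:
            a5, a3 = config.qpcr_integrity
            integ = qpcr_mod.integrity_table(records, a5, a3)
            integ.to_csv(out / "qpcr_integrity.csv")
        expr = qpcr_mod.expression_table(records, config.qpcr_reference)
        expr.to_csv(out / "qpcr_expression.csv", index=False)
        tests = qpcr_mod.paired_tests_by_target(expr, config.control, config.treated)
        tests.to_csv(out / "qpcr_tests.csv")
        summary["qpcr_targets"] = sorted(tests.index)

    _dump_json(summary, out / "summary.json")
    return summary
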