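"""Simulator contracts: determinism, degradation mechanics, mismatch truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rna_dryqc.annotation import POLYA_FREE_BIOTYPES
from rna_dryqc.qc import read_sam
from rna_dryqc.simulate import (
    GroupSpec,
    MismatchSpec,
    SimulationConfig,
    generate_annotation,
    simulate_library,
)


class TestGenerateAnnotation:
    def test_fixed_seed_is_byte_identical(self, tmp_path, small_config):
        paths = []
        for i in (1, 2):
            ann = generate_annotation(small_config)
            gtf, fa = tmp_path / f"g{i}.gtf", tmp_path / f"g{i}.fa"
            ann.write_gtf(gtf)
            ann.write_fasta(fa)
            paths.append((gtf.read_bytes(), fa.read_bytes()))
        assert paths[0] == paths[1]

    def test_empty_annotation_is_valid(self, tmp_path):
        ann = generate_annotation(SimulationConfig(seed=3, n_genes=0))
        assert ann.genes == []
        ann.write_gtf(tmp_path / "e.gtf")
        ann.write_fasta(tmp_path / "e.fa")
        assert (tmp_path / "e.gtf").read_text() == ""
        assert (tmp_path / "e.fa").read_text().startswith(">chr1")

    def test_biotype_mix_within_binomial_error(self):
        cfg = SimulationConfig(seed=5, n_genes=100,
                               biotype_mix={"protein_coding": 0.9, "snoRNA": 0.1})
        ann = generate_annotation(cfg)
        n_sno = sum(g.biotype == "snoRNA" for g in ann.genes)
        # 10 +- 3 binomial SEs
        assert abs(n_sno - 10) <= 3 * np.sqrt(100 * 0.1 * 0.9)
        # exact count reproducible for the seed
        again = sum(g.biotype == "snoRNA" for g in generate_annotation(cfg).genes)
        assert n_sno == again

    def test_genes_do_not_overlap_and_both_strands_present(self, small_annotation):
        by_chrom = {}
        for g in small_annotation.genes:
            meta = small_annotation.metas[g.gene_id]
            by_chrom.setdefault(g.chromosome, []).append((meta.starts[0], meta.ends[-1]))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        assert {g.strand for g in small_annotation.genes} == {"+", "-"}


class TestSimulateLibrary:
    def test_fixed_seed_sam_is_byte_identical(self, tmp_path, small_config, small_annotation):
        contents = []
        for i in (1, 2):
            lib = simulate_library(small_annotation, small_config, "control", 0)
            p = tmp_path / f"s{i}.sam"
            lib.write_sam(small_annotation, p)
            contents.append(p.read_bytes())
        assert contents[0] == contents[1]

    def test_polya_free_genes_yield_no_reads(self, small_experiment, small_annotation):
        polya_free = {g.gene_id for g in small_annotation.genes if g.biotype in POLYA_FREE_BIOTYPES}
        lib = small_experiment["control_0"]
        assert polya_free, "fixture should contain poly(A)-free genes"
        assert not set(lib.truth_reads["gene_id"]) & polya_free

    def test_full_decay_yields_zero_reads(self, small_annotation, small_config):
        import dataclasses
        captured = [g.gene_id for g in small_annotation.genes
                    if g.biotype not in POLYA_FREE_BIOTYPES]
        victim = frozenset({captured[0]})
        cfg = dataclasses.replace(
            small_config,
            groups=(GroupSpec("control"), GroupSpec("lyo", decay_p=1.0, affected_genes=victim)),
        )
        lib = simulate_library(small_annotation, cfg, "lyo", 0)
        assert captured[0] not in set(lib.truth_reads["gene_id"])
        row = lib.truth_genes.set_index("gene_id").loc[captured[0]]
        assert row["dropped_decay"] == row["molecules"]

    def test_duplicate_fraction_and_conservation(self, small_experiment):
        lib = small_experiment["control_0"]
        n_dup = int(lib.truth_reads["duplicate"].sum())
        n_tot = len(lib.truth_reads)
        assert n_tot == len(lib.reads)
        assert abs(n_dup / n_tot - lib.config.duplication) < 0.01
        dup_ids = {r.read_id for r in lib.reads if r.is_duplicate}
        originals = {(r.chromosome, r.blocks, r.seq) for r in lib.reads if not r.is_duplicate}
        for r in lib.reads:
            if r.read_id in dup_ids:
                assert (r.chromosome, r.blocks, r.seq) in originals

    def test_no_degradation_gives_uniform_five_prime_ends(self, small_experiment, small_annotation):
        lib = small_experiment["control_0"]
        rl = lib.config.read_length
        truth = lib.truth_reads[~lib.truth_reads["duplicate"]]
        by_gene = truth.groupby("gene_id").size().sort_values(ascending=False)
        target = by_gene.index[0]
        assert by_gene.iloc[0] >= 500
        L = small_annotation.metas[target].length
        m = truth.loc[truth["gene_id"] == target, "meta_pos"].to_numpy(float)
        # KS against uniform over the feasible placement range
        stat = stats.kstest((m + 0.5) / (L - rl + 1), "uniform")
        assert stat.pvalue > 0.01

    def test_cleavage_shifts_ends_three_prime_ward(self, small_annotation, small_config):
        import dataclasses
        cfg = dataclasses.replace(
            small_config,
            groups=(GroupSpec("control"), GroupSpec("lyo", cleavage_events=1.0)),
        )
        ctrl = simulate_library(small_annotation, cfg, "control", 0)
        trt = simulate_library(small_annotation, cfg, "lyo", 0)
        gene = ctrl.truth_reads.groupby("gene_id").size().idxmax()
        mc = ctrl.truth_reads.loc[ctrl.truth_reads["gene_id"] == gene, "meta_pos"]
        mt = trt.truth_reads.loc[trt.truth_reads["gene_id"] == gene, "meta_pos"]
        assert len(mc) >= 500 and len(mt) >= 300
        res = stats.mannwhitneyu(mt, mc, alternative="greater")
        assert res.pvalue < 0.01

    def test_injected_mismatch_rate_recovered(self, small_annotation, small_config):
        import dataclasses
        cfg = dataclasses.replace(
            small_config,
            depth=20_000,
            base_mismatch_rate=0.0,
            mismatches=(MismatchSpec("C", "T", 0.01, (1, 10)),),
        )
        lib = simulate_library(small_annotation, cfg, "control", 0)
        n_ct_early = n_ct_late = 0
        c_at = np.zeros(cfg.read_length)
        for r in lib.reads:
            if r.is_duplicate:
                continue
            refseq = list(r.seq)
            for p, rb, ab in r.mismatches:
                refseq[p - 1] = rb
                if rb == "C" and ab == "T":
                    if p <= 10:
                        n_ct_early += 1
                    else:
                        n_ct_late += 1
            for p0, b in enumerate(refseq):
                if b == "C":
                    c_at[p0] += 1
        den = c_at[:10].sum()
        rate = n_ct_early / den
        se = np.sqrt(0.01 * 0.99 / den)
        assert abs(rate - 0.01) < 3 * se
        assert n_ct_late == 0

    def test_sam_round_trip_preserves_reads_and_mismatches(self, tmp_path, small_experiment, small_annotation):
        lib = small_experiment["lyo_1"]
        p = tmp_path / "rt.sam"
        lib.write_sam(small_annotation, p)
        reads, totals = read_sam(p)
        assert totals.mapped == len(lib.reads)
        parsed = {r.read_id: r for r in reads}
        for r in lib.reads[:500]:
            q = parsed[r.read_id]
            assert q.blocks == r.blocks
            assert q.seq == r.seq
            assert q.mismatches == tuple(sorted(r.mismatches))
            assert q.is_duplicate == r.is_duplicate

    def test_mismatch_records_agree_with_reference_fasta(self, small_experiment, small_annotation):
        lib = small_experiment["control_2"]
        seqs = small_annotation.seqs
        checked = 0
        for r in lib.reads[:300]:
            # reconstruct genomic-orientation read and compare to the genome
            genomic = r.seq if r.strand == "+" else _rc(r.seq)
            offset = 0
            ref = "".join(seqs[r.chromosome][s:e] for s, e in r.blocks)
            mism_sam = set()
            L = len(r.seq)
            for p, rb, ab in r.mismatches:
                if r.strand == "+":
                    mism_sam.add((p - 1, rb))
                else:
                    mism_sam.add((L - p, _rc(rb)))
            for i, (gb, rb) in enumerate(zip(genomic, ref)):
                if gb != rb:
                    assert (i, rb) in mism_sam
                    checked += 1
        assert checked > 0


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1] if len(s) > 1 else s.translate(str.maketrans("ACGT", "TGCA"))
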