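"""Simulator-driven validation suite.

Each check re-runs the relevant pipeline stage on synthetic libraries with
known ground truth (or against an independent brute-force oracle) and returns
the observed quantity together with the problem size.  The checks are the
package's acceptance properties; the test suite asserts their bounds and the
acceptance script reports their values.

Problem sizes are desk-scale by design: a few hundred genes and 1e4-5e5 reads
per library, enough for each statistical bound while keeping a full run in
minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import coverage as cov_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import qc as qc_mod
from . import qpcr as qpcr_mod
from .pipeline import RunConfig, run_pipeline
from .simulate import (
    Annotation,
    GroupSpec,
    MismatchSpec,
    SimulationConfig,
    generate_annotation,
    simulate_experiment,
)


def _assignments(annotation: Annotation, libs) -> dict[str, pd.DataFrame]:
    index = annotation.index()
    return {sid: index.assign_reads(lib.reads) for sid, lib in libs.items()}


def _classify_all(annotation, libs, gene_ids, control="control", treated="lyo", alpha=0.01):
    groups = {sid: lib.group for sid, lib in libs.items()}
    assignments = _assignments(annotation, libs)
    table, _ = bias_mod.classify_genes(
        assignments, annotation.metas, gene_ids, groups, control, treated, alpha=alpha
    )
    return table, assignments


def check_bias_type1(seed: int) -> dict:
    """Null classifier calibration: no degradation, equal expression.

    400 genes, 3 vs 3 samples, ~100 reads/gene/sample; fraction of classified
    genes called non-uniform at alpha = 0.01 should sit in the 95% binomial
    band [0.002, 0.025] around alpha.  The depth is chosen where per-bin
    ratios are close enough to Gaussian for the OLS slope t-test to hold its
    nominal level; at very low counts the test runs conservative.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=400,
        expression_sdlog=0.0,
        depth=400 * 100,
        groups=(GroupSpec("control"), GroupSpec("lyo")),
    )
    ann = generate_annotation(cfg)
    libs = simulate_experiment(ann, cfg)
    table, _ = _classify_all(ann, libs, [g.gene_id for g in ann.genes])
    classified = table[table["bias_class"] != bias_mod.UNCLASSIFIABLE]
    nonuniform = (classified["bias_class"] != bias_mod.UNIFORM).sum()
    return {"value": float(nonuniform / len(classified)), "n": int(len(classified))}


def check_bias_power(seed: int) -> dict:
    """Power against cleavage: one expected cut per molecule, treated only.

    100 genes, ~220 reads/gene/sample.  Expect >= 80% of genes classified
    5'-underrepresented and essentially no 3' calls.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=100,
        expression_sdlog=0.0,
        depth=100 * 220,
        groups=(GroupSpec("control"), GroupSpec("lyo", cleavage_events=1.0)),
    )
    ann = generate_annotation(cfg)
    libs = simulate_experiment(ann, cfg)
    table, _ = _classify_all(ann, libs, [g.gene_id for g in ann.genes])
    classified = table[table["bias_class"] != bias_mod.UNCLASSIFIABLE]
    n = len(classified)
    five = (classified["bias_class"] == bias_mod.FIVE_PRIME).sum()
    three = (classified["bias_class"] == bias_mod.THREE_PRIME).sum()
    return {"five_prime_fraction": float(five / n), "three_prime_count": int(three), "n": int(n)}


def check_fold_recovery(seed: int) -> dict:
    """Uniform decay p = 0.5 on 50 of 100 equally expressed genes.

    The decayed genes lose half their molecules while the library total
    shrinks by a quarter, so the expected control/treated FPKM fold is
    2 * (1 - 0.25) = 1.5.  The same genes should look *uniform* to the bias
    classifier (decay has no positional preference).
    """
    n_genes = 100
    decayed = frozenset(f"G{i:04d}" for i in range(50))
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        biotype_mix={"protein_coding": 1.0},
        expression_sdlog=0.0,
        depth=n_genes * 220,
        groups=(GroupSpec("control"), GroupSpec("lyo", decay_p=0.5, affected_genes=decayed)),
    )
    ann = generate_annotation(cfg)
    libs = simulate_experiment(ann, cfg)
    assignments = _assignments(ann, libs)
    gene_ids = [g.gene_id for g in ann.genes]
    counts = expr_mod.counts_matrix(assignments, gene_ids)
    lengths = pd.Series({g: ann.metas[g].length for g in gene_ids}, dtype=float)
    biotypes = pd.Series({g.gene_id: g.biotype for g in ann.genes})
    fpkm = expr_mod.filter_expressed(expr_mod.fpkm(counts, lengths), biotypes)
    groups = {sid: lib.group for sid, lib in libs.items()}
    cmp = expr_mod.group_comparison(fpkm, groups, "control", "lyo", de_genes=sorted(decayed))
    table, _ = bias_mod.classify_genes(
        assignments, ann.metas, sorted(decayed), groups, "control", "lyo", alpha=0.01
    )
    classified = table[table["bias_class"] != bias_mod.UNCLASSIFIABLE]
    nonuniform_frac = float((classified["bias_class"] != bias_mod.UNIFORM).mean())
    return {
        "median_fold": float(cmp.fold_median),
        "nonuniform_fraction": nonuniform_frac,
        "n": int(len(cmp.folds)),
    }


def _diversity_oracle(counts: pd.Series, ranks) -> dict[int, float]:
    """Brute-force sort-and-sum, independent of the library implementation."""
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(v for _, v in items)
    out = {}
    for k in ranks:
        out[int(k)] = sum(v for _, v in items[: int(k)]) / total
    return out


def check_diversity_oracle(seed: int, n_tables: int = 1000) -> dict:
    """Exact agreement with the sort-and-sum oracle on random count tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    tested = 0
    for _ in range(n_tables):
        n = int(rng.integers(5, 200))
        counts = pd.Series(rng.poisson(5.0, size=n), index=[f"g{i}" for i in range(n)], dtype=float)
        if counts.sum() == 0:
            continue
        ranks = (1, 3, 10, 100, 10000)
        got = cov_mod.cumulative_gene_diversity(counts, ranks=ranks).fractions
        want = _diversity_oracle(counts, ranks)
        worst = max(worst, max(abs(got[k] - want[k]) for k in ranks))
        tested += 1
    return {"value": float(worst), "n": tested}


def check_fpkm_identity(seed: int) -> dict:
    """sum_g FPKM_g * L_g(kb) == 1e6 per sample, to 1e-6 relative."""
    cfg = SimulationConfig(seed=seed, n_genes=80, depth=20_000)
    ann = generate_annotation(cfg)
    libs = simulate_experiment(ann, cfg)
    assignments = _assignments(ann, libs)
    gene_ids = [g.gene_id for g in ann.genes]
    counts = expr_mod.counts_matrix(assignments, gene_ids)
    lengths = pd.Series({g: ann.metas[g].length for g in gene_ids}, dtype=float)
    fpkm = expr_mod.fpkm(counts, lengths)
    identity = (fpkm.mul(lengths / 1000.0, axis=0)).sum(axis=0)
    rel_err = (identity - 1.0e6).abs() / 1.0e6
    return {"value": float(rel_err.max()), "n": int(counts.to_numpy().sum())}


def check_coverage_flatness(seed: int) -> dict:
    """Null gene-body coverage: every bin fraction within [0.020, 0.030].

    Long single-exon genes (~20 kb) keep the read-length edge deficit in the
    final bins far below the band width; one sample at a depth giving >=1e5
    reads on the upper-middle-quartile gene set.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=40,
        mean_exons=1.0,
        exon_length=(18_000, 22_000),
        expression_sdlog=0.0,
        depth=480_000,
        groups=(GroupSpec("control", n_samples=1),),
    )
    ann = generate_annotation(cfg)
    lib = simulate_experiment(ann, cfg)["control_0"]
    index = ann.index()
    assignments = index.assign_reads(lib.reads)
    counts, _, _ = expr_mod.count_reads(assignments, [g.gene_id for g in ann.genes])
    umq = cov_mod.select_upper_middle_quartile(counts)
    prof = cov_mod.gene_body_coverage(assignments, ann.metas, umq, sample_id=lib.sample_id)
    return {
        "min_bin": float(prof.fractions.min()),
        "max_bin": float(prof.fractions.max()),
        "n": int(prof.n_reads),
    }


def check_mismatch_recovery(seed: int) -> dict:
    """Injected C>T excess (rate 0.02, cycles 1-10) in the treated group only.

    3 vs 3 samples of 1e5 reads: count how many of the 10 injected cells are
    significant at 5% BH FDR across all 12 x 75 cells.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=10,
        expression_sdlog=0.5,
        depth=100_000,
        duplication=0.0,
        groups=(
            GroupSpec("control"),
            GroupSpec("lyo", extra_mismatches=(MismatchSpec("C", "T", 0.02, (1, 10)),)),
        ),
    )
    ann = generate_annotation(cfg)
    libs = simulate_experiment(ann, cfg)
    profiles = {sid: qc_mod.mismatch_profile(lib.reads, sample_id=sid) for sid, lib in libs.items()}
    cmp = qc_mod.compare_mismatch_profiles(
        [profiles[f"control_{i}"] for i in range(3)],
        [profiles[f"lyo_{i}"] for i in range(3)],
        fdr=0.05,
    )
    hits = cmp[(cmp["type"] == "C>T") & (cmp["position"] <= 10) & cmp["significant"]]
    return {"value": int(len(hits)), "n": 10}


def check_mismatch_null_fdr(seed: int, n_reps: int = 100) -> dict:
    """100 null repetitions: fraction with any BH-significant cell ~ 5%.

    Small libraries (4 genes, 6e3 reads/sample) keep the whole loop fast; the
    bound tested downstream is <= 10 of 100 repetitions (binomial slack
    around 0.05).
    """
    reps_with_hit = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=(seed * 1009 + rep) % (2**31 - 1),
            n_genes=4,
            mean_exons=1.0,
            exon_length=(900, 1200),
            depth=6_000,
            duplication=0.0,
            groups=(GroupSpec("control"), GroupSpec("lyo")),
        )
        ann = generate_annotation(cfg)
        libs = simulate_experiment(ann, cfg)
        profiles = {sid: qc_mod.mismatch_profile(lib.reads, sample_id=sid) for sid, lib in libs.items()}
        cmp = qc_mod.compare_mismatch_profiles(
            [profiles[f"control_{i}"] for i in range(3)],
            [profiles[f"lyo_{i}"] for i in range(3)],
            fdr=0.05,
        )
        reps_with_hit += bool(cmp["significant"].any())
    return {"value": int(reps_with_hit), "n": n_reps}


def _mw_enumeration_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney P by full enumeration of labelings."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx_set):
        rsum = sum(ranks[pooled[i]] for i in idx_set)
        return rsum - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    p_ge = sum(u >= u_obs for u in us) / total
    p_le = sum(u <= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def check_mw_oracle(seed: int) -> dict:
    """Exact Mann-Whitney equals full enumeration for all n1+n2 <= 10."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    tested = 0
    for n1 in range(1, 10):
        for n2 in range(1, 11 - n1):
            for _ in range(3):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0) + rng.random(n1 + n2) * 0.1)
                a, b = vals[:n1], vals[n1:]
                _, p = enr_mod.mann_whitney(a, b)
                p_oracle = _mw_enumeration_oracle(a, b)
                worst = max(worst, abs(p - p_oracle))
                tested += 1
    return {"value": float(worst), "n": tested}


def check_qpcr_closed_forms() -> dict:
    """Hand-checkable qPCR identities via the independent E^-Cp route."""
    r5 = qpcr_mod.QPCRRecord("s1", "control", "p1", "GAPDH5", (21.0,), 2.0)
    r3 = qpcr_mod.QPCRRecord("s1", "control", "p1", "GAPDH3", (20.0,), 2.0)
    ratio_e2 = qpcr_mod.integrity_ratio(r5, r3).ratio  # one cycle of 3' excess doubles
    t = qpcr_mod.QPCRRecord("s1", "control", "p1", "TGT", (25.0,), 2.0)
    ref = qpcr_mod.QPCRRecord("s1", "control", "p1", "ACTB", (20.0,), 2.0)
    expr_e2 = qpcr_mod.relative_expression(t, ref)
    t19 = qpcr_mod.QPCRRecord("s1", "control", "p1", "TGT", (25.0,), 1.9)
    expr_mixed = qpcr_mod.relative_expression(t19, ref)
    # independent closed forms: template scales as E^-Cp, so ratios of
    # amplified quantities never touch the log2 rescaling route
    err = max(
        abs(ratio_e2 - (2.0**-20.0) / (2.0**-21.0)),
        abs(expr_e2 - (2.0**-25.0) / (2.0**-20.0)),
        abs(expr_mixed - (1.9**-25.0) / (2.0**-20.0)),
    )
    return {"value": float(err), "ratio_e2": float(ratio_e2), "expr_mixed": float(expr_mixed), "n": 3}


# ---------------------------------------------------------------------------
# End-to-end fixture and determinism
# ---------------------------------------------------------------------------


def make_pipeline_fixture(outdir, seed: int) -> RunConfig:
    """Write a small but complete input set (SAM/GTF/FASTA/DE/ARE/Cp tables)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    degraded = frozenset(f"G{i:04d}" for i in range(12))
    cfg = SimulationConfig(
        seed=seed,
        n_genes=30,
        depth=4_000,
        groups=(
            GroupSpec("control"),
            GroupSpec("lyo", decay_p=0.35, cleavage_per_kb=1.2, affected_genes=degraded),
        ),
    )
    ann = generate_annotation(cfg)
    ann.write_gtf(out / "genes.gtf")
    ann.write_fasta(out / "genome.fa")
    libs = simulate_experiment(ann, cfg)
    sam = {}
    for sid, lib in libs.items():
        path = out / f"{sid}.sam"
        lib.write_sam(ann, path)
        sam[sid] = str(path)
    de = sorted(g.gene_id for g in ann.genes
                if g.gene_id in degraded and g.biotype == "protein_coding")
    (out / "de_genes.txt").write_text("\n".join(de) + "\n")
    rng = np.random.default_rng(seed + 17)
    are = pd.DataFrame(
        {
            "gene_id": de,
            "are_3utr": rng.random(len(de)) < 0.5,
            "are_intron": rng.random(len(de)) < 0.3,
        }
    )
    are.to_csv(out / "are.tsv", sep="\t", index=False)
    rows = []
    for pair in range(3):
        for group in ("control", "lyo"):
            s = f"{group}_{pair}"
            base = 20.0 + rng.normal(0, 0.3)
            for target, off, eff in (
                ("GAPDH5", 1.0, 1.95),
                ("GAPDH3", 1.0 if group == "control" else 0.7, 1.95),
                ("ACTB", -2.0, 2.0),
                ("TCL1A", 6.0, 1.9),
            ):
                cps = base + off + rng.normal(0, 0.1, size=3)
                rows.append(
                    dict(
                        sample=s, group=group, pair_id=f"p{pair}", target=target,
                        cp_rep1=round(cps[0], 3), cp_rep2=round(cps[1], 3), cp_rep3=round(cps[2], 3),
                        efficiency=eff,
                    )
                )
    pd.DataFrame(rows).to_csv(out / "cp_table.csv", index=False)
    groups = {sid: lib.group for sid, lib in libs.items()}
    return RunConfig(
        gtf=str(out / "genes.gtf"),
        fasta=str(out / "genome.fa"),
        sam=sam,
        groups=groups,
        control="control",
        treated="lyo",
        de_list=str(out / "de_genes.txt"),
        are_table=str(out / "are.tsv"),
        cp_table=str(out / "cp_table.csv"),
        qpcr_integrity=("GAPDH5", "GAPDH3"),
        outdir=str(out / "run"),
        seed=seed,
    )


def check_determinism(seed: int, workdir) -> dict:
    """Two pipeline runs on the same fixed-seed fixture are byte-identical."""
    work = Path(workdir)
    cfg = make_pipeline_fixture(work / "fixture", seed)
    diffs = []
    outs = []
    for i in (1, 2):
        c = dataclasses.replace(cfg, outdir=str(work / f"run{i}"))
        run_pipeline(c)
        outs.append(Path(c.outdir))
    names = sorted(p.name for p in outs[0].iterdir())
    names2 = sorted(p.name for p in outs[1].iterdir())
    if names != names2:
        diffs.append("file lists differ")
    else:
        for name in names:
            if (outs[0] / name).read_bytes() != (outs[1] / name).read_bytes():
                diffs.append(name)
    return {"value": int(not diffs), "n": len(names), "differing": diffs}
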