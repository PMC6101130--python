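# rna-dryqc

Degradation-aware quality control for poly(A)-selected RNA-seq, built for
studies that compare a preservation or storage treatment against paired
controls (lyophilized vs. fresh cells, FFPE vs. frozen, storage time
courses).  It answers two questions a standard QC report does not: *did the
treatment degrade the RNA*, and *by which mechanism* — strand cleavage,
which under poly(A) capture strips 5' ends from the library, or
whole-molecule decay, which depletes a transcript evenly?

The package implements, at desk scale and against a ground-truth simulator:

* **library QC** — uniquely-mapped fraction, duplication rate, per-read GC
  histograms, chromosomal read distribution, detected genes, and the 30%
  deviation-from-median outlier rule;
* **positional mismatch profiles** — substitution rates per (type, read
  cycle) conditional on the reference base, compared between groups with a
  variance-moderated Welch t-test at 5% Benjamini–Hochberg FDR;
* **gene-body coverage** in 40 × 2.5% meta-transcript bins for
  upper-middle-quartile genes, and **cumulative gene diversity** (read
  fraction on the top 10/100/1000/10000 genes);
* **expression** — union-exon gene counting, FPKM with the exact identity
  Σ FPKM·L_kb = 10⁶, the FPKM ≥ 1 / poly(A)-free biotype filter, group-mean
  log₂ scatter R² and per-gene folds;
* **the 40-bin degradation-bias classifier** — per-gene treated/control bin
  ratios regressed on bin index; slope t-test at α = 0.01 labels each gene
  `uniform`, `five_prime_underrepresented` or `three_prime_underrepresented`;
* **transcript-feature enrichment** — Mann–Whitney U comparison of
  length/%GC features (transcript, cDNA, CDS, UTRs) between an affected
  gene set and the annotation background, plus the ARE/bias overlap counts;
* **qPCR arithmetic** — efficiency-corrected Cp (Cp' = Cp·log₂E), the
  GAPDH-style 3'/5' integrity ratio 2^−ΔCp', ΔCp relative expression
  normalized to a reference gene, and paired group tests;
* **a synthetic-library simulator** — paired control/treated groups of
  single-end 75-bp poly(A)-selected reads with per-gene uniform decay,
  Poisson cleavage (3'-terminal fragment retained), PCR duplication and
  position/type-specific mismatches, emitting SAM plus full truth tables.

The core statistic: for gene *g* with meta-transcript length *L* (union of
exons, 5'→3'), each read contributes its 5'-end meta-position *m* to bin
⌊40·m/L⌋.  With group-mean bin counts c̄ᵢ (control) and t̄ᵢ (treated), the
ratios rᵢ = t̄ᵢ/c̄ᵢ over bins with c̄ᵢ > 0 are fit by OLS, rᵢ = α + βi;
P(β = 0) < 0.01 with β > 0 means the 5' end is underrepresented in the
treated library — the fragmentation signature.

## Worked example

Simulate a 2 × 3 experiment (30 genes, 4 000 molecules/sample) in which the
treated ("lyo") group degrades 12 genes by both decay (p = 0.35) and
cleavage (1.2 cuts/kb), write SAM/GTF/FASTA plus qPCR and ARE tables, and
run the full pipeline:

```python
import tempfile
from rna_dryqc.validation import make_pipeline_fixture
from rna_dryqc.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = make_pipeline_fixture(tmp, seed=42)
    summary = run_pipeline(cfg)
    print(summary["r_squared"], summary["bias_classes"])
```

Output of this exact run:

```
R2 0.9274
bias {'five_prime_underrepresented': 9, 'uniform': 1}
mismatch significant cells: 0
fold_median 1.381   fold range [1.145, 1.552]   n_de 10
qPCR integrity ratio, group means:  control 1.065   lyo 1.257
ARE/bias overlap {'both': 6, 'are_only': 1, 'bias_only': 3, 'neither': 0}
```

Reading: expression of the two groups still correlates well (R² = 0.93)
and no mismatch cell differs — degradation does not corrupt base calls —
but the ten differentially affected protein-coding genes show folds of
1.1–1.6 (control/treated), nine of ten carry a significant positive bin
slope (5' underrepresentation, the cleavage fingerprint; e.g. G0000:
β = 0.045, P < 10⁻⁴ over 35 usable bins), and the treated group's
qPCR 3'/5' ratio is elevated (1.26 vs 1.07).  That is the full signature
of fragmentation-driven degradation plus uniform decay.

Every stage is also exposed on the command line:

```
rna-dryqc simulate --config sim.yaml --outdir data/
rna-dryqc qc --sam data/control_0.sam ... --gtf data/genes.gtf --out qc/
rna-dryqc bias --sam ... --groups control,...,lyo --gtf data/genes.gtf \
               --genes de_genes.txt --alpha 0.01 --out bias/
rna-dryqc run --config pipeline.yaml
rna-dryqc validate --seed 1 --full
```

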