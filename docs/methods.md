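# Methods

`rna-dryqc` asks a single scientific question of a paired RNA-seq experiment:
*did a treatment (storage, preservation, fixation) degrade the RNA, and if
so, by which mechanism?*  Under poly(A)-selected library preparation the two
canonical decay routes leave different footprints:

* **strand cleavage / fragmentation** — a cut molecule keeps its poly(A)
  tail only on the 3'-terminal fragment, so cleaved 5' ends are washed off
  the capture beads and the 5' half of the transcript is underrepresented in
  the library;
* **regulated whole-molecule decay** (e.g. ARE-mediated deadenylation) —
  molecules disappear wholesale, depleting a gene evenly along its length,
  visible as an expression fold change with *no* positional signature.

Every stage of the pipeline is built to separate these two signatures from
ordinary technical variation.

## Coordinate model

All genomic arithmetic is 0-based half-open internally; GTF is read and
written 1-based closed.  Each gene is reduced to a **meta-transcript**: the
union of all its annotated exons, indexed 5'→3' (meta-position 0 is the
genomic left end for `+` genes and the genomic right end for `-` genes).
The map between genomic and meta coordinates is a bijection over exonic
bases, which the test suite checks exhaustively on multi-exon fixtures.
Feature computation (lengths and %GC of transcript, cDNA, CDS, 5'UTR,
3'UTR) uses the gene's longest transcript variant, with ties broken by
transcript id; zero-length regions are reported absent rather than as 0% GC.

## The 40-bin degradation-bias classifier

For each gene, each sample's reads are binned by the meta-position *m* of
the read 5' end into bin `floor(40·m/L)` (bin 1 = 5' end).  Bin counts are
averaged within groups and the per-bin ratio r_i = treated/control is
regressed on bin index by ordinary least squares.  The two-sided t-test of
slope = 0 at α = 0.01 gives the class:

| condition            | class                        |
|----------------------|------------------------------|
| P ≥ α                | uniform                      |
| P < α, slope > 0     | five_prime_underrepresented  |
| P < α, slope < 0     | three_prime_underrepresented |

Choices that were genuinely open, and how they were resolved:

* **5'-end binning.** A read contributes only its 5'-end bin, not its whole
  footprint.  This keeps the statistic monotone under 5' loss and makes the
  uniform-placement null exactly computable.
* **Zero-control bins are masked, not pseudocounted.**  Pseudocounts drag
  low-abundance genes' ratios toward a spurious slope; masking only costs
  degrees of freedom.  A gene needs ≥ 10 usable bins to be classified;
  below that it is reported `unclassifiable` with the reason.
* **No cross-gene multiple-testing correction** for the classification
  itself (the per-gene α = 0.01 convention); a BH q-value column is emitted
  for users who want one.
* **Limitation:** ratios of low counts are heteroscedastic and the OLS
  assumes they are not.  The classifier is calibrated empirically instead:
  on null simulations (400 genes, 3 vs 3 samples, ~50 reads/gene/sample)
  the non-uniform fraction at α = 0.01 falls inside the 95% binomial band
  [0.002, 0.025], and label swap flips the slope sign exactly.

## Expression and folds

Counting is union-exon and gene-level: a read is assigned iff any alignment
block overlaps exactly one gene's merged exons; multi-gene overlaps are
discarded as ambiguous.  FPKM uses the per-sample total of *assigned* reads
M, giving the exact identity Σ_g FPKM_g·L_g/1000 = 10⁶ per sample (tested to
1e-6 relative).  The expression filter keeps genes with FPKM ≥ 1 in at least
one sample (the boundary is kept) and drops poly(A)-free small-RNA biotypes
(snRNA, snoRNA, scaRNA, vtRNA, snaR, miRNA), whose capture under poly(A)
selection is ambiguous.  Folds are oriented control/treated so genes lost in
the treated group have fold > 1.  Isoform deconvolution is deliberately out
of scope: folds here are descriptive, not a DE test.

## Mismatch profiling and the moderated test

Substitutions are tallied per (type, read position) in sequencing-cycle
orientation (reverse-strand alignments are flipped and complemented), with
the denominator conditional on the source reference base — a rate per
opportunity.  Duplicate-flagged reads are excluded from profiles (they would
double-count the same molecule) but included in duplication-rate numerators;
expression counting includes them.  Both policies are configurable.

Group comparison is a Welch-style t-test per cell with one modification: the
per-group variance is **moderated toward the binomial sampling floor**
mean_i[p(1−p)/den_i] with a prior of df₀ = 4,

    s² = ((n−1)·v_emp + df₀·v_floor) / (n−1+df₀),   df = n−1+df₀,

combined across groups by Welch–Satterthwaite, then BH-corrected over all
12 × read-length cells at 5% FDR.  The floor is not optional at desk-scale
depth: a rate observed over a finite denominator carries sampling variance
p(1−p)/d even when the counts agree exactly across replicates, and the raw
n−1 estimator collapses to ~0 under count discreteness, producing
astronomically anticonservative tails.  With the floor the test is
calibrated (0/100 null repetitions with any BH discovery) while recovering
10/10 injected C>T positions at Δε = 0.02 with 3 × 10⁵-read samples.  As
the number of replicates grows the moderated estimate converges to the plain
Welch test.

## qPCR arithmetic

An assay with amplification efficiency E (fold per cycle, 1 < E ≤ 2)
implies template ∝ E^−Cp.  Rescaling to base 2 via Cp' = Cp·log₂E is the
unique correction under which the conventional 2^−ΔCp formulas apply across
assays of different efficiency.  Replicates are averaged on the Cp scale
(geometric mean of quantities).  The 3'/5' integrity ratio 2^−(Cp'₃−Cp'₅)
equals 1 for intact RNA and rises under degradation; relative expression is
2^−(Cp'target−Cp'ref), normalized to a reference gene (ACTB by default).
Degenerate paired t-tests (zero-variance differences) return P = 1 for a
zero shift and P = 0 otherwise, by documented convention.  No-RT controls
within 5 cycles of the RT Cp are flagged, never auto-excluded.

## The synthetic-data generator

The simulator emulates the study design the pipeline targets: two groups ×
three replicates of poly(A)-selected, single-end 75-bp, unstranded
libraries.  Per sample, per-gene molecule counts are multinomial over
captured genes given lognormal expression θ; each molecule then passes
through:

1. **uniform decay** — discarded with probability p (per group, optionally
   per gene subset);
2. **cleavage** — Poisson(λ·L/1000) cuts uniform along the molecule; only
   the 3'-terminal fragment survives capture (the max-of-uniforms gives the
   retained-segment start in closed form);
3. **read placement** — the 5' end uniform over retained positions that
   admit a full-length read; molecules whose retained segment is shorter
   than the read are dropped and counted;
4. **mismatch injection** — configurable (type, cycle-range) rates on top
   of a uniform error floor (default 10⁻³/base);
5. **PCR duplication** — a fraction d (default 0.10) of output records are
   resampled copies carrying the SAM 0x400 flag.

Reads map back to genomic coordinates through the meta-transcript (split
over junctions, `N` CIGAR gaps), and SAM output is coordinate-sorted with
NH=1 and NM/MD tags.  All randomness derives from (seed, group, sample
index), so libraries are byte-reproducible.  Poly(A)-free biotypes are
transcribed but not captured unless a config switch says otherwise.

What the generator does *not* model — and hence what passing tests cannot
show about real data: base-quality structure (all bases maximal quality),
alignment error and multi-mapping, splice-isoform switching, GC-dependent
amplification bias, positional fragmentation bias of intact libraries, and
biological replicate-to-replicate dispersion beyond sampling noise.  The
calibration and power numbers are statements about the estimators under the
model's idealized noise, not about any particular instrument.

Default scales are desk-sized by design (10²–10⁵ reads per library,
tens to hundreds of genes); the validation suite states each check's size
explicitly:

| check | conditions |
|---|---|
| classifier type-I | 400 genes, 3 v 3, ~50 reads/gene/sample, no degradation |
| classifier power | 100 genes, λ·L = 1 treated only, ~220 reads/gene/sample |
| fold recovery | 100 genes, p = 0.5 decay on 50, ~220 reads/gene/sample |
| coverage flatness | 40 single-exon ~20 kb genes, 4.8×10⁵ molecules, 1 sample |
| mismatch recovery | 10 genes, 3 v 3 × 10⁵ reads, Δε = 0.02 at cycles 1–10 |
| null FDR | 100 reps of 4 genes, 3 v 3 × 6×10³ reads |

The coverage-flatness check uses ~20 kb genes because 5' ends are placed on
[0, L−75]: the final bins are structurally depleted by ~75/L of a bin width,
which only drops below the [0.020, 0.030] band's resolution when L ≫ 40·75.
The expected fold in the decay check is 2·(1−0.25) = 1.5, not 1/(1−p) = 2,
because halving 50 of 100 equally expressed genes also shrinks the library
normalizer M by a quarter.

## Numerical conventions

* Outlier rule: a sample is flagged when |value − median|/median ≥ 0.30 for
  any QC metric (the 30% boundary counts as an outlier); zero-median
  metrics are skipped with a warning.
* Upper-middle-quartile gene selection: linear-interpolation percentiles
  over expressed (count > 0) genes, interval closed at P50 and open at P75;
  complete ties collapse P50 = P75 and select the tied genes.
* Diversity curves break count ties by gene id for determinism; ranks
  beyond the gene count report fraction 1.
* Mann-Whitney U: exact null distribution when n₁·n₂ ≤ 400 with no ties
  (verified against full enumeration for all n₁+n₂ ≤ 10), otherwise normal
  approximation with midranks, tie-corrected variance and continuity
  correction.
* Constant-ratio genes get slope 0, P = 1 (uniform); numerically exact
  lines get P = 0.
* Abundance strata by FPKM: high > 100, moderate 10–100, low 1–10,
  extremely low < 1.
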