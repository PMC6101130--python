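"""Synthetic degraded poly(A)-selected RNA-seq libraries with ground truth.

The generator emulates the study design the pipeline targets: two groups
(control vs. treated) of three replicates each, single-end 75-bp reads from a
poly(A)-captured library, with two distinct degradation mechanisms:

* *uniform decay*: each molecule of a gene is lost with probability p,
  depleting the gene evenly along its length (ARE-mediated-decay-like);
* *strand cleavage*: cut positions arrive as a Poisson process at rate
  lambda per kb along the transcript; only the 3'-terminal fragment keeps the
  poly(A) tail and survives capture, so the 5' end is underrepresented
  (fragmentation-like).

PCR duplication is modelled by resampling emitted records with replacement
and setting the SAM 0x400 flag; mismatches are injected at configurable
(type, read-position) rates on top of a small uniform error floor.  All
randomness derives from (seed, group, sample index), so a given library is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .annotation import (
    POLYA_FREE_BIOTYPES,
    GeneModel,
    GenomeIndex,
    MetaTranscript,
    TranscriptModel,
    build_meta_transcript,
    revcomp,
    write_gtf,
)
from .qc import AlignedRead

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MismatchSpec:
    """Inject ref>alt substitutions at ``rate`` over a 1-based cycle range."""

    ref: str
    alt: str
    rate: float
    positions: tuple[int, int] | None = None  # inclusive; None = whole read


@dataclass(frozen=True)
class GroupSpec:
    """Degradation settings for one sample group.

    ``cleavage_events`` (expected cuts per molecule, length-independent)
    overrides ``cleavage_per_kb`` when set.  ``affected_genes`` restricts the
    degradation to a subset; None degrades every captured gene.
    """

    name: str
    n_samples: int = 3
    decay_p: float = 0.0
    cleavage_per_kb: float = 0.0
    cleavage_events: float | None = None
    affected_genes: frozenset | None = None
    extra_mismatches: tuple[MismatchSpec, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic libraries.

    Defaults mirror the design the pipeline was built around: 2 groups x 3
    replicates, poly(A)-selected single-end 75-bp reads, lognormal expression,
    and a modest PCR duplication fraction, at desk-scale depth.
    """

    seed: int = 0
    n_genes: int = 100
    biotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.70,
            "lncRNA": 0.14,
            "pseudogene": 0.06,
            "snoRNA": 0.04,
            "snRNA": 0.03,
            "miRNA": 0.03,
        }
    )
    mean_exons: float = 3.0
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (60, 300)
    intergenic_gap: tuple[int, int] = (100, 400)
    min_transcript_length: int = 200
    expression_meanlog: float = 0.0
    expression_sdlog: float = 1.0
    read_length: int = 75
    depth: int = 50_000
    duplication: float = 0.10
    base_mismatch_rate: float = 0.001
    mismatches: tuple[MismatchSpec, ...] = ()
    groups: tuple[GroupSpec, ...] = (GroupSpec("control"), GroupSpec("lyo"))
    capture_polya_free: bool = False

    def __post_init__(self) -> None:
        total = sum(self.biotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_mix proportions sum to {total}, expected 1")
        if not 0 <= self.duplication < 1:
            raise ValueError("duplication must be in [0, 1)")
        for g in self.groups:
            if not 0 <= g.decay_p <= 1:
                raise ValueError(f"group {g.name}: decay_p outside [0, 1]")
            if g.cleavage_per_kb < 0 or (g.cleavage_events is not None and g.cleavage_events < 0):
                raise ValueError(f"group {g.name}: cleavage rate must be >= 0")

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown group {name!r}; configured: {[g.name for g in self.groups]}")


class Annotation:
    """A toy genome plus its gene models and derived per-gene caches."""

    def __init__(self, genes: list[GeneModel], seqs: dict[str, str], theta: pd.Series) -> None:
        self.genes = genes
        self.seqs = seqs
        self.theta = theta
        self.metas: dict[str, MetaTranscript] = {g.gene_id: build_meta_transcript(g) for g in genes}
        self._tseq_codes: dict[str, np.ndarray] = {}

    def tseq_codes(self, gene_id: str) -> np.ndarray:
        """Transcript (meta) sequence as base codes 0..3, 5'->3'."""
        if gene_id not in self._tseq_codes:
            seq = self.metas[gene_id].sequence(self.seqs)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            codes = np.searchsorted(_LETTERS, arr)  # ACGT are sorted byte values
            self._tseq_codes[gene_id] = codes.astype(np.uint8)
        return self._tseq_codes[gene_id]

    def index(self) -> GenomeIndex:
        return GenomeIndex(self.genes)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.seqs):
                fh.write(f">{chrom}\n")
                s = self.seqs[chrom]
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")

    def write_gtf(self, path) -> None:
        write_gtf(self.genes, path)

    def write_theta(self, path) -> None:
        self.theta.rename("theta").to_csv(path, sep="\t")


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Place non-overlapping genes on two toy chromosomes and draw expression.

    Deterministic for a fixed seed: the same config yields byte-identical GTF
    and FASTA output.  Protein-coding genes get a CDS flanked by UTRs (~10%
    5'UTR, ~20% 3'UTR of the transcript), so feature computation is exercised.
    """
    rng = np.random.default_rng(config.seed)
    chroms = ["chr1", "chr2"]
    cursors = {c: 0 for c in chroms}
    genes: list[GeneModel] = []
    mix = sorted(config.biotype_mix.items())
    mix_names = [b for b, _ in mix]
    mix_p = np.array([p for _, p in mix])
    min_len = max(config.min_transcript_length, config.read_length + 25)
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        biotype = mix_names[rng.choice(len(mix_names), p=mix_p)]
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = chroms[i % len(chroms)]
        n_ex = 1 + int(rng.poisson(max(config.mean_exons - 1.0, 0.0)))
        lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        deficit = min_len - int(lens.sum())
        if deficit > 0:
            lens[-1] += deficit
        introns = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=max(n_ex - 1, 0))
        start = cursors[chrom] + int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        exons = []
        pos = start
        for j, ln in enumerate(lens):
            exons.append((pos, pos + int(ln)))
            pos += int(ln)
            if j < n_ex - 1:
                pos += int(introns[j])
        cursors[chrom] = pos
        tx = TranscriptModel(f"{gid}.t1", exons=exons)
        if biotype == "protein_coding":
            meta = MetaTranscript(gid, chrom, strand, exons)
            tlen = meta.length
            u5 = max(1, round(0.10 * tlen))
            u3 = max(1, round(0.20 * tlen))
            tx.cds = meta.meta_interval_blocks(u5, tlen - u3)
        genes.append(GeneModel(gid, biotype, chrom, strand, transcripts=[tx]))
    seqs = {}
    for chrom in chroms:
        n = cursors[chrom] + 200
        seqs[chrom] = _LETTERS[rng.integers(0, 4, size=n)].tobytes().decode()
    theta = pd.Series(
        rng.lognormal(config.expression_meanlog, config.expression_sdlog, size=config.n_genes),
        index=[g.gene_id for g in genes],
        dtype=float,
    )
    return Annotation(genes, seqs, theta)


@dataclass
class SimulatedLibrary:
    """One sample's reads plus the per-gene and per-read ground truth."""

    sample_id: str
    group: str
    config: SimulationConfig
    reads: list[AlignedRead]
    truth_genes: pd.DataFrame
    truth_reads: pd.DataFrame

    def write_sam(self, annotation: Annotation, path) -> None:
        write_sam(self.reads, annotation, path)

    def write_truth(self, genes_path, reads_path) -> None:
        self.truth_genes.to_csv(genes_path, sep="\t", index=False)
        self.truth_reads.to_csv(reads_path, sep="\t", index=False)


def _gene_degradation(spec: GroupSpec, gene_id: str, length: int) -> tuple[float, float]:
    """(decay probability, expected cleavage events per molecule) for a gene."""
    if spec.affected_genes is not None and gene_id not in spec.affected_genes:
        return 0.0, 0.0
    if spec.cleavage_events is not None:
        return spec.decay_p, spec.cleavage_events
    return spec.decay_p, spec.cleavage_per_kb * length / 1000.0


def simulate_library(
    annotation: Annotation, config: SimulationConfig, group: str, sample_index: int
) -> SimulatedLibrary:
    """Molecule-level simulation of one library.

    Per gene, molecule counts are multinomial given theta over captured genes;
    each molecule is discarded with its decay probability, cleaved by a
    Poisson(lambda_g * L/1000) number of uniform cut positions of which only
    the 3'-terminal segment is retained, and yields one read whose 5' end is
    uniform over retained positions admitting a full-length read.  Molecules
    whose retained segment is shorter than the read are dropped and counted.
    """
    spec = config.group(group)
    g_idx = [g.name for g in config.groups].index(group)
    rng = np.random.default_rng((config.seed, 7000 + g_idx, sample_index))
    sample_id = f"{group}_{sample_index}"
    rl = config.read_length

    captured = [
        g
        for g in annotation.genes
        if config.capture_polya_free or g.biotype not in POLYA_FREE_BIOTYPES
    ]
    for g in captured:
        if annotation.metas[g.gene_id].length < rl:
            raise ValueError(f"gene {g.gene_id}: meta-transcript shorter than the read length")
    if captured:
        th = annotation.theta[[g.gene_id for g in captured]].to_numpy()
        counts = rng.multinomial(config.depth, th / th.sum())
    else:
        counts = np.array([], dtype=int)

    specs = tuple(config.mismatches) + tuple(spec.extra_mismatches)
    reads: list[AlignedRead] = []
    truth_read_rows: list[tuple] = []
    truth_gene_rows: list[tuple] = []
    serial = 0
    for gene, n_mol in zip(captured, counts):
        gid = gene.gene_id
        meta = annotation.metas[gid]
        L = meta.length
        p_decay, lam_events = _gene_degradation(spec, gid, L)
        n_surv = int(rng.binomial(n_mol, 1.0 - p_decay)) if n_mol else 0
        dropped_decay = int(n_mol) - n_surv
        dropped_short = 0
        m = np.empty(0, dtype=np.int64)
        if n_surv:
            k = rng.poisson(lam_events, size=n_surv)
            u = rng.random(n_surv)
            # retained 3' segment starts at the max of k uniform cuts on (0, L)
            cut = np.where(k > 0, L * u ** (1.0 / np.maximum(k, 1)), 0.0)
            lo = np.ceil(cut).astype(np.int64)
            hi = L - rl
            keep = lo <= hi
            dropped_short = int(n_surv - keep.sum())
            lo = lo[keep]
            if lo.size:
                m = rng.integers(lo, hi + 1)
        truth_gene_rows.append(
            (gid, gene.biotype, float(annotation.theta[gid]), p_decay, lam_events, L,
             int(n_mol), dropped_decay, dropped_short, int(m.size))
        )
        if m.size == 0:
            continue
        tcodes = annotation.tseq_codes(gid)
        ref_mat = tcodes[m[:, None] + np.arange(rl)[None, :]]
        read_mat = ref_mat.copy()
        for ms in specs:
            colmask = np.ones(rl, dtype=bool)
            if ms.positions is not None:
                colmask[:] = False
                colmask[ms.positions[0] - 1 : ms.positions[1]] = True
            hit = (ref_mat == _BASE_INDEX[ms.ref]) & colmask[None, :] & (rng.random(read_mat.shape) < ms.rate)
            read_mat[hit] = _BASE_INDEX[ms.alt]
        if config.base_mismatch_rate > 0:
            untouched = read_mat == ref_mat
            bmask = untouched & (rng.random(read_mat.shape) < config.base_mismatch_rate)
            shift = rng.integers(1, 4, size=read_mat.shape, dtype=np.uint8)
            read_mat[bmask] = (ref_mat[bmask] + shift[bmask]) % 4
        seq_bytes = _LETTERS[read_mat].tobytes()
        ref_bytes = _LETTERS[ref_mat].tobytes()
        diff_rows = np.flatnonzero((read_mat != ref_mat).any(axis=1))
        mism_by_row: dict[int, tuple] = {}
        for i in diff_rows:
            cols = np.flatnonzero(read_mat[i] != ref_mat[i])
            mism_by_row[int(i)] = tuple(
                (int(c) + 1, chr(ref_bytes[i * rl + c]), chr(seq_bytes[i * rl + c])) for c in cols
            )
        single_block = len(meta.blocks) == 1
        for i in range(m.size):
            mi = int(m[i])
            if single_block:
                if meta.strand == "+":
                    gs = int(meta.starts[0]) + mi
                else:
                    gs = int(meta.starts[0]) + L - mi - rl
                blocks = ((gs, gs + rl),)
            else:
                blocks = tuple(meta.meta_interval_blocks(mi, mi + rl))
            rid = f"{sample_id}.{serial}"
            serial += 1
            mm = mism_by_row.get(i, ())
            reads.append(
                AlignedRead(
                    read_id=rid,
                    chromosome=meta.chromosome,
                    blocks=blocks,
                    strand=meta.strand,
                    seq=seq_bytes[i * rl : (i + 1) * rl].decode(),
                    is_unique=True,
                    is_duplicate=False,
                    mismatches=mm,
                )
            )
            truth_read_rows.append(
                (rid, gid, mi, False, ";".join(f"{p}:{rb}>{ab}" for p, rb, ab in mm))
            )

    # PCR duplicates: resample emitted records with replacement so that the
    # duplicate fraction of the final library is ~config.duplication
    n_unique = len(reads)
    d = config.duplication
    n_dup = int(round(n_unique * d / (1.0 - d))) if n_unique and d > 0 else 0
    if n_dup:
        idx = rng.integers(0, n_unique, size=n_dup)
        gid_of = {row[0]: (row[1], row[2], row[4]) for row in truth_read_rows}
        for j, i in enumerate(idx):
            src = reads[int(i)]
            rid = f"{sample_id}.d{j}"
            reads.append(replace(src, read_id=rid, is_duplicate=True))
            g, mp, mmstr = gid_of[src.read_id]
            truth_read_rows.append((rid, g, mp, True, mmstr))

    truth_genes = pd.DataFrame(
        truth_gene_rows,
        columns=["gene_id", "biotype", "theta", "decay_p", "cleavage_events", "length",
                 "molecules", "dropped_decay", "dropped_short", "unique_reads"],
    )
    truth_reads = pd.DataFrame(
        truth_read_rows, columns=["read_id", "gene_id", "meta_pos", "duplicate", "mismatches"]
    )
    return SimulatedLibrary(sample_id, group, config, reads, truth_genes, truth_reads)


def simulate_experiment(annotation: Annotation, config: SimulationConfig) -> dict[str, SimulatedLibrary]:
    """All samples of all groups, keyed by sample_id (deterministic order)."""
    out: dict[str, SimulatedLibrary] = {}
    for g in config.groups:
        for s in range(g.n_samples):
            lib = simulate_library(annotation, config, g.name, s)
            out[lib.sample_id] = lib
    return out


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------


def _md_and_nm(read: AlignedRead) -> tuple[str, int]:
    """MD tag (genomic orientation) and NM from the read's mismatch records."""
    L = read.length
    if read.strand == "+":
        items = sorted((p - 1, rb) for p, rb, _ in read.mismatches)
    else:
        items = sorted((L - p, rb.translate(_RC)) for p, rb, _ in read.mismatches)
    md = []
    prev = 0
    for off, rb in items:
        md.append(str(off - prev))
        md.append(rb)
        prev = off + 1
    md.append(str(L - prev))
    return "".join(md), len(items)


_RC = str.maketrans("ACGT", "TGCA")


def write_sam(reads, annotation: Annotation, path) -> None:
    """Coordinate-sorted SAM with NH=1, MD/NM tags and 0x400 duplicate flags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(annotation.seqs[c])} for c in sorted(annotation.seqs)],
    }
    tid = {c: i for i, c in enumerate(sorted(annotation.seqs))}
    ordered = sorted(reads, key=lambda r: (tid[r.chromosome], r.blocks[0][0], r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for r in ordered:
            a = pysam.AlignedSegment(af.header)
            a.query_name = r.read_id
            flag = 0
            if r.strand == "-":
                flag |= 16
            if r.is_duplicate:
                flag |= 0x400
            a.flag = flag
            a.reference_id = tid[r.chromosome]
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 50
            cig = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cig.append(f"{s - prev_end}N")
                cig.append(f"{e - s}M")
                prev_end = e
            a.cigarstring = "".join(cig)
            a.query_sequence = r.seq if r.strand == "+" else revcomp(r.seq)
            md, nm = _md_and_nm(r)
            a.set_tags([("NH", 1), ("NM", nm), ("MD", md)])
            af.write(a)
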