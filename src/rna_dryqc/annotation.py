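"""Gene models, meta-transcripts and transcript features.

A *meta-transcript* is the union of all exonic intervals of a gene, read in
5'->3' order, used as a single per-gene coordinate system: meta-position 0 is
the transcript 5' end (the genomic left end for '+' genes, the genomic right
end for '-' genes).  Under poly(A) selection, degradation by strand cleavage
removes 5' meta-positions from the library, which is what the downstream bias
classifier quantifies.

Internal coordinates are 0-based half-open throughout; GTF is read and written
in its native 1-based closed convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Controlled biotype vocabulary.  Anything else is mapped to "other".
BIOTYPES = frozenset(
    {
        "protein_coding",
        "lncRNA",
        "pseudogene",
        "snRNA",
        "snoRNA",
        "scaRNA",
        "vtRNA",
        "snaR",
        "miRNA",
        "other",
    }
)

#: Small-RNA classes not reliably captured by poly(A) selection; excluded by
#: the expression filter and (by default) not captured by the simulator.
POLYA_FREE_BIOTYPES = frozenset({"snRNA", "snoRNA", "scaRNA", "vtRNA", "snaR", "miRNA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and non-overlapping.

    Adjacent (abutting) intervals are merged as well, so the result is the
    minimal disjoint representation.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"interval has start >= end: [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TranscriptModel:
    """One annotated transcript: exons plus (for coding genes) CDS intervals."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] | None = None

    @property
    def length(self) -> int:
        """Exonic (cDNA) length in nt."""
        return sum(e - s for s, e in merge_intervals(self.exons))


@dataclass
class GeneModel:
    """A gene: strand-aware exon structure shared by all its transcripts."""

    gene_id: str
    biotype: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            logger.warning("gene %s: unknown biotype %r mapped to 'other'", self.gene_id, self.biotype)
            self.biotype = "other"

    @property
    def exons(self) -> list[tuple[int, int]]:
        """All exon intervals over all transcripts (possibly overlapping)."""
        return [iv for tx in self.transcripts for iv in tx.exons]

    def longest_transcript(self) -> TranscriptModel:
        """Longest transcript by exonic nt; ties broken by transcript_id."""
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        return min(self.transcripts, key=lambda t: (-t.length, t.transcript_id))


class MetaTranscript:
    """Union of a gene's exons as a single strand-aware coordinate system."""

    __slots__ = ("gene_id", "chromosome", "strand", "blocks", "starts", "ends", "cum", "length")

    def __init__(self, gene_id: str, chromosome: str, strand: str, blocks) -> None:
        self.gene_id = gene_id
        self.chromosome = chromosome
        self.strand = strand
        self.blocks = merge_intervals(blocks)
        self.starts = np.array([s for s, _ in self.blocks], dtype=np.int64)
        self.ends = np.array([e for _, e in self.blocks], dtype=np.int64)
        lens = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lens)])
        self.length = int(self.cum[-1])

    def genomic_to_meta(self, chromosome: str, position: int) -> int | None:
        """Offset of a genomic position from the transcript 5' end.

        Counts exonic bases only; returns None for intronic/intergenic
        positions or the wrong chromosome.
        """
        if chromosome != self.chromosome:
            return None
        i = int(np.searchsorted(self.starts, position, side="right")) - 1
        if i < 0 or position >= self.ends[i]:
            return None
        plus_offset = int(self.cum[i]) + int(position) - int(self.starts[i])
        if self.strand == "+":
            return plus_offset
        return self.length - 1 - plus_offset

    def meta_to_genomic(self, m: int) -> int:
        """Genomic coordinate of meta-position ``m`` (0-based)."""
        if not 0 <= m < self.length:
            raise IndexError(f"meta-position {m} outside [0, {self.length})")
        p = m if self.strand == "+" else self.length - 1 - m
        j = int(np.searchsorted(self.cum, p, side="right")) - 1
        return int(self.starts[j]) + p - int(self.cum[j])

    def meta_interval_blocks(self, m0: int, m1: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending) covering meta-interval [m0, m1)."""
        if not 0 <= m0 < m1 <= self.length:
            raise IndexError(f"meta-interval [{m0}, {m1}) outside [0, {self.length})")
        if self.strand == "+":
            p0, p1 = m0, m1
        else:
            p0, p1 = self.length - m1, self.length - m0
        out: list[tuple[int, int]] = []
        j = int(np.searchsorted(self.cum, p0, side="right")) - 1
        while p0 < p1:
            take = min(int(self.cum[j + 1]), p1) - p0
            gs = int(self.starts[j]) + p0 - int(self.cum[j])
            out.append((gs, gs + take))
            p0 += take
            j += 1
        return out

    def sequence(self, seqs) -> str:
        """5'->3' meta-transcript sequence given a chromosome-sequence source."""
        parts = [str(seqs[self.chromosome][s:e]) for s, e in self.blocks]
        plus = "".join(parts).upper()
        return plus if self.strand == "+" else revcomp(plus)


def build_meta_transcript(gene: GeneModel) -> MetaTranscript:
    """Meta-transcript from the union of all the gene's exons."""
    exons = gene.exons
    if not exons:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    return MetaTranscript(gene.gene_id, gene.chromosome, gene.strand, exons)


# ---------------------------------------------------------------------------
# GTF I/O (ENSEMBL dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> list[GeneModel]:
    """Read an ENSEMBL-dialect GTF into GeneModel objects.

    Only exon, CDS and stop_codon features are consumed.  Coordinates are
    converted from 1-based closed to 0-based half-open.  Unknown biotypes are
    mapped to "other" with a warning; a malformed line raises with its line
    number.
    """
    genes: dict[str, GeneModel] = {}
    tx_of_gene: dict[str, dict[str, TranscriptModel]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinates") from exc
            if s < 0 or e <= s:
                raise ValueError(f"{path}: malformed GTF line {lineno}: invalid interval {start}-{end}")
            a = _parse_attributes(attrs)
            gid = a.get("gene_id")
            tid = a.get("transcript_id")
            if not gid or not tid:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id/transcript_id")
            biotype = a.get("gene_biotype") or a.get("transcript_biotype") or a.get("biotype") or "other"
            if gid not in genes:
                genes[gid] = GeneModel(gid, biotype, chrom, strand)
                tx_of_gene[gid] = {}
            gene = genes[gid]
            if gene.chromosome != chrom or gene.strand != strand:
                raise ValueError(f"{path}: line {lineno}: gene {gid} spans chromosomes/strands")
            txs = tx_of_gene[gid]
            if tid not in txs:
                txs[tid] = TranscriptModel(tid)
                gene.transcripts.append(txs[tid])
            tx = txs[tid]
            if feature == "exon":
                tx.exons.append((s, e))
            else:  # CDS or stop_codon: both count toward the coding span
                if tx.cds is None:
                    tx.cds = []
                tx.cds.append((s, e))
    for gene in genes.values():
        for tx in gene.transcripts:
            tx.exons = merge_intervals(tx.exons)
            if tx.cds is not None:
                tx.cds = merge_intervals(tx.cds)
    return sorted(genes.values(), key=lambda g: g.gene_id)


def write_gtf(genes, path) -> None:
    """Write GeneModels as ENSEMBL-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                base = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{gene.chromosome}\trna_dryqc\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{base}\n"
                    )
                for s, e in tx.cds or []:
                    fh.write(
                        f"{gene.chromosome}\trna_dryqc\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t{base}\n"
                    )


# ---------------------------------------------------------------------------
# Transcript features
# ---------------------------------------------------------------------------


def _region_features(seq: str | None) -> dict[str, float | int | None]:
    if seq is None or len(seq) == 0:
        # zero-length region is reported absent, not as 0% GC
        return {"length": None, "gc": None, "gc_pct": None}
    gc = gc_count(seq)
    return {"length": len(seq), "gc": gc, "gc_pct": 100.0 * gc / len(seq)}


def transcript_features(gene: GeneModel, seqs) -> dict:
    """Length and GC features for the gene's longest transcript variant.

    ``seqs`` maps chromosome name to a sliceable sequence (dict of str, or a
    pyfaidx.Fasta).  For coding transcripts the cDNA is split into 5'UTR, CDS
    and 3'UTR by the CDS span in transcript coordinates, so the three lengths
    (and GC counts) sum to the cDNA values.
    """
    tx = gene.longest_transcript()
    meta = MetaTranscript(tx.transcript_id, gene.chromosome, gene.strand, tx.exons)
    try:
        tseq = meta.sequence(seqs)
    except KeyError as exc:
        raise KeyError(f"missing sequence for {gene.chromosome} (gene {gene.gene_id})") from exc
    out: dict = {
        "gene_id": gene.gene_id,
        "biotype": gene.biotype,
        "transcript_id": tx.transcript_id,
    }
    whole = _region_features(tseq)
    out.update({f"transcript_{k}": v for k, v in whole.items()})
    if tx.cds:
        offsets = []
        for s, e in tx.cds:
            m0 = meta.genomic_to_meta(gene.chromosome, s)
            m1 = meta.genomic_to_meta(gene.chromosome, e - 1)
            if m0 is None or m1 is None:
                raise ValueError(f"{gene.gene_id}: CDS interval [{s},{e}) not within exons")
            offsets.extend([m0, m1])
        c0, c1 = min(offsets), max(offsets) + 1
        regions = {"utr5": tseq[:c0], "cds": tseq[c0:c1], "utr3": tseq[c1:]}
        for name, seq in regions.items():
            out.update({f"{name}_{k}": v for k, v in _region_features(seq).items()})
        out["cdna_length"] = len(tseq)
        out["cdna_gc"] = whole["gc"]
        out["cdna_gc_pct"] = whole["gc_pct"]
    return out


def feature_table(genes, seqs) -> pd.DataFrame:
    """Per-gene feature records (longest transcript variant), as a DataFrame."""
    rows = [transcript_features(g, seqs) for g in genes if g.transcripts]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Genome index: read -> gene assignment and meta-positions
# ---------------------------------------------------------------------------

AMBIGUOUS = "__ambiguous__"


class GenomeIndex:
    """Interval index over gene merged exons for read assignment.

    A read is assigned to a gene iff any alignment block overlaps the gene's
    merged exons; reads overlapping exons of more than one gene are ambiguous
    and assigned to none.
    """

    def __init__(self, genes) -> None:
        self.genes = {g.gene_id: g for g in genes}
        self.metas = {g.gene_id: build_meta_transcript(g) for g in genes}
        self.trees: dict[str, IntervalTree] = {}
        for gid, meta in self.metas.items():
            tree = self.trees.setdefault(meta.chromosome, IntervalTree())
            for s, e in meta.blocks:
                tree.addi(s, e, gid)

    def assign(self, chromosome: str, blocks) -> str | None:
        tree = self.trees.get(chromosome)
        if tree is None:
            return None
        hits: set[str] = set()
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
                if len(hits) > 1:
                    return AMBIGUOUS
        if not hits:
            return None
        return next(iter(hits))

    def meta_position(self, gene_id: str, chromosome: str, position: int) -> int | None:
        return self.metas[gene_id].genomic_to_meta(chromosome, position)

    def assign_reads(self, reads) -> pd.DataFrame:
        """Assignment table for an iterable of AlignedRead.

        Columns: read_id, gene_id (None/AMBIGUOUS allowed), meta_pos (5'-end
        meta-position; -1 when unassigned or non-exonic), duplicate.
        """
        rows = []
        for r in reads:
            gid = self.assign(r.chromosome, r.blocks)
            mpos = -1
            if gid is not None and gid != AMBIGUOUS:
                five = r.blocks[0][0] if r.strand == "+" else r.blocks[-1][1] - 1
                m = self.metas[gid].genomic_to_meta(r.chromosome, five)
                if m is not None:
                    mpos = m
            rows.append((r.read_id, gid, mpos, r.is_duplicate))
        return pd.DataFrame(rows, columns=["read_id", "gene_id", "meta_pos", "duplicate"])
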