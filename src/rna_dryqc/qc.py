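"""Per-sample library metrics and positional mismatch profiles.

Reads come in as single-end, unstranded alignments (SAM).  Mismatch positions
are always reported in sequencing-cycle orientation: for reverse-strand
alignments the position is flipped and both bases complemented, so that
chemistry- or cycle-dependent substitution structure lines up across reads
regardless of which genomic strand they hit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AMBIGUOUS, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
#: The 12 substitution types, ref != alt, in fixed report order.
MISMATCH_TYPES = tuple(f"{r}>{a}" for r in _BASES for a in _BASES if r != a)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(slots=True)
class AlignedRead:
    """One mapped single-end read.

    ``seq`` and ``mismatches`` are in read (cycle) orientation; ``blocks`` are
    genomic 0-based half-open intervals in ascending order.  Mismatch records
    are (1-based read position, reference base, read base).
    """

    read_id: str
    chromosome: str
    blocks: tuple
    strand: str
    seq: str
    is_unique: bool = True
    is_duplicate: bool = False
    mismatches: tuple = ()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SamTotals:
    total: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    mapped: int = 0
    unique: int = 0


def read_sam(path, mapq_threshold: int = 10, fasta=None):
    """Read a SAM file into AlignedRead records plus record totals.

    Unmapped, secondary and supplementary records are excluded from the read
    list but counted in the totals.  Mismatches are derived from the MD tag
    (via pysam); if MD is absent a reference FASTA must be supplied.
    Uniqueness uses the NH tag when present, else MAPQ >= ``mapq_threshold``.
    """
    reads: list[AlignedRead] = []
    totals = SamTotals()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for aln in af:
            totals.total += 1
            if aln.is_unmapped:
                totals.unmapped += 1
                continue
            if aln.is_secondary:
                totals.secondary += 1
                continue
            if aln.is_supplementary:
                totals.supplementary += 1
                continue
            totals.mapped += 1
            seq = aln.query_sequence or ""
            n = len(seq)
            try:
                pairs = aln.get_aligned_pairs(with_seq=True)
            except ValueError:
                if fasta is None:
                    raise ValueError(
                        f"{path}: record {aln.query_name} lacks an MD tag and no "
                        "reference FASTA was supplied; pass fasta= to derive mismatches"
                    ) from None
                ref = {}
                for s, e in aln.get_blocks():
                    chunk = str(fasta[aln.reference_name][s:e]).upper()
                    for off, base in enumerate(chunk):
                        ref[s + off] = base
                pairs = [
                    (q, r, ref.get(r, "N").lower() if r is not None and q is not None and ref.get(r, "N") != seq[q] else ref.get(r))
                    for q, r in aln.get_aligned_pairs()
                ]
            mm = []
            for q, r, refbase in pairs:
                if q is None or r is None or refbase is None:
                    continue
                if refbase.islower():  # pysam lower-cases reference mismatches
                    mm.append((q, refbase.upper(), seq[q]))
            if aln.is_reverse:
                cycle_seq = revcomp(seq)
                mism = tuple(
                    sorted((n - q, refb.translate(_RC1), alt.translate(_RC1)) for q, refb, alt in mm)
                )
            else:
                cycle_seq = seq
                mism = tuple((q + 1, refb, alt) for q, refb, alt in mm)
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality >= mapq_threshold
            totals.unique += unique
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chromosome=aln.reference_name,
                    blocks=tuple(aln.get_blocks()),
                    strand="-" if aln.is_reverse else "+",
                    seq=cycle_seq,
                    is_unique=unique,
                    is_duplicate=aln.is_duplicate,
                    mismatches=mism,
                )
            )
    return reads, totals


_RC1 = str.maketrans("ACGT", "TGCA")


@dataclass
class LibraryMetrics:
    sample_id: str
    group: str
    total_records: int
    mapped: int
    unique_fraction: float
    duplication_rate: float
    gc_histogram: np.ndarray
    chromosome_fractions: dict[str, float]
    detected_genes: int | None = None

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "group": self.group,
            "total_records": self.total_records,
            "mapped": self.mapped,
            "unique_fraction": self.unique_fraction,
            "duplication_rate": self.duplication_rate,
            "chromosome_fractions": self.chromosome_fractions,
            "gc_histogram": [int(x) for x in self.gc_histogram],
        }
        if self.detected_genes is not None:
            d["detected_genes"] = self.detected_genes
        return d


def library_metrics(reads, totals: SamTotals, sample_id: str = "", group: str = "", detected_genes: int | None = None) -> LibraryMetrics:
    """Library-level QC metrics from the mapped primary reads.

    unique_fraction is relative to all records (the usual "fraction of
    sequencing reads mapping uniquely"); duplication_rate is duplicate-flagged
    over mapped.  The GC histogram uses 1% bins over per-read GC fraction.
    """
    if totals.total < 1:
        raise ValueError("empty SAM: no records")
    n_mapped = len(reads)
    dup = sum(r.is_duplicate for r in reads)
    gc = np.array([100.0 * (r.seq.count("G") + r.seq.count("C")) / max(r.length, 1) for r in reads])
    hist, _ = np.histogram(gc, bins=np.linspace(0.0, 100.0, 101))
    chrom_counts: dict[str, int] = {}
    for r in reads:
        chrom_counts[r.chromosome] = chrom_counts.get(r.chromosome, 0) + 1
    fractions = {c: k / n_mapped for c, k in sorted(chrom_counts.items())} if n_mapped else {}
    return LibraryMetrics(
        sample_id=sample_id,
        group=group,
        total_records=totals.total,
        mapped=n_mapped,
        unique_fraction=totals.unique / totals.total,
        duplication_rate=dup / n_mapped if n_mapped else 0.0,
        gc_histogram=hist,
        chromosome_fractions=fractions,
        detected_genes=detected_genes,
    )


def deviation_from_median(metrics: pd.DataFrame, threshold: float = 0.30):
    """Signed relative deviation from the per-metric median, plus outlier flags.

    ``metrics`` is samples x metrics.  A sample is an outlier iff its absolute
    deviation reaches ``threshold`` (default 30%, boundary inclusive) for any
    metric.  Metrics whose median is zero are skipped with a warning.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 samples to call outliers against a median")
    dev = {}
    for col in metrics.columns:
        med = metrics[col].median()
        if med == 0:
            warnings.warn(f"metric {col!r}: median is 0, deviation undefined; skipped")
            continue
        dev[col] = (metrics[col] - med) / med
    deviations = pd.DataFrame(dev, index=metrics.index)
    outliers = (deviations.abs() >= threshold).any(axis=1)
    return deviations, outliers


@dataclass
class MismatchProfile:
    """rate[t, p] for the 12 substitution types over read positions 1..L."""

    sample_id: str
    read_length: int
    rates: np.ndarray  # (12, L)
    denominators: np.ndarray  # (12, L): aligned bases whose reference base is the type's source
    numerators: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, typ in enumerate(MISMATCH_TYPES):
            for p in range(self.read_length):
                rows.append((typ, p + 1, self.rates[t, p], int(self.denominators[t, p])))
        return pd.DataFrame(rows, columns=["type", "position", "rate", "denominator"])


def mismatch_profile(reads, sample_id: str = "", include_duplicates: bool = False) -> MismatchProfile:
    """Positional substitution rates, conditional on the source reference base.

    rate(X>Y, p) = (# X>Y mismatches at cycle p) / (# aligned cycles p whose
    reference base is X).  Duplicate-flagged reads are excluded from both the
    numerator and the denominator by default.  Zero-denominator cells report
    rate 0.
    """
    use = [r for r in reads if include_duplicates or not r.is_duplicate]
    if not use:
        raise ValueError("no reads available for mismatch profiling")
    L = max(r.length for r in use)
    if any(r.length != L for r in use):
        raise ValueError("mismatch profiling requires uniform read length")
    mat = np.frombuffer("".join(r.seq for r in use).encode(), dtype=np.uint8)
    codes = _CODE[mat].reshape(len(use), L)
    ref = codes.copy()
    num = np.zeros((12, L), dtype=np.int64)
    type_index = {t: i for i, t in enumerate(MISMATCH_TYPES)}
    for i, r in enumerate(use):
        for pos1, refb, alt in r.mismatches:
            ref[i, pos1 - 1] = _CODE[ord(refb)]
            key = f"{refb}>{alt}"
            if key in type_index:
                num[type_index[key], pos1 - 1] += 1
    base_den = np.stack([(ref == b).sum(axis=0) for b in range(4)])  # (4, L)
    den = np.zeros((12, L), dtype=np.int64)
    for t, typ in enumerate(MISMATCH_TYPES):
        den[t] = base_den[_BASES.index(typ[0])]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return MismatchProfile(sample_id=sample_id, read_length=L, rates=rates, denominators=den, numerators=num)


#: Prior degrees of freedom given to the binomial variance floor when
#: moderating the per-cell empirical variance (see _group_moments).
FLOOR_PRIOR_DF = 4.0


def _group_moments(profiles):
    """(mean rate, per-mean variance component, df) per (type, position).

    A rate observed over denominator d carries binomial sampling variance
    p(1-p)/d even when the counts happen to agree exactly across samples, so
    the raw n-1 variance estimate is unusable at low depth: count
    discreteness makes it collapse to ~0 and the t tails become wildly
    anticonservative.  The group variance is therefore moderated toward the
    binomial floor mean_i[ p(1-p)/den_i ] with FLOOR_PRIOR_DF prior degrees
    of freedom,

        s^2 = ((n-1) v_emp + df0 v_floor) / (n - 1 + df0),  df = n - 1 + df0,

    which reduces to the plain Welch estimate as n grows and to the known
    sampling floor when the replicates are exhausted.
    """
    n = len(profiles)
    R = np.stack([p.rates for p in profiles])  # (n, 12, L)
    D = np.stack([p.denominators for p in profiles]).astype(float)
    mean = R.mean(axis=0)
    v_emp = R.var(axis=0, ddof=1)
    v_floor = (mean[None, :, :] * (1.0 - mean[None, :, :]) / np.maximum(D, 1.0)).mean(axis=0)
    df_emp = float(n - 1)
    var = (df_emp * v_emp + FLOOR_PRIOR_DF * v_floor) / (df_emp + FLOOR_PRIOR_DF)
    df = np.full(mean.shape, df_emp + FLOOR_PRIOR_DF)
    return mean, var / n, df


def compare_mismatch_profiles(profiles_a, profiles_b, fdr: float = 0.05) -> pd.DataFrame:
    """Per (type, position) moderated Welch t-test of rates between groups.

    Per-group variances are moderated toward the binomial sampling floor
    (see _group_moments) and combined with Welch-Satterthwaite degrees of
    freedom.  Benjamini-Hochberg correction is applied across all 12 x
    read-length cells; cells with no variance and equal means get P = 1 by
    convention.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need >=2 samples per group to compare mismatch profiles")
    L = profiles_a[0].read_length
    mean_a, ca, dfa = _group_moments(profiles_a)
    mean_b, cb, dfb = _group_moments(profiles_b)
    denom = ca + cb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / np.sqrt(denom)
        df_den = np.where(np.isinf(dfa), 0.0, ca**2 / np.where(np.isinf(dfa), 1.0, dfa)) + np.where(
            np.isinf(dfb), 0.0, cb**2 / np.where(np.isinf(dfb), 1.0, dfb)
        )
        df = np.where(df_den > 0, denom**2 / np.maximum(df_den, 1e-300), np.inf)
        pv = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(pv)  # denom == 0: all rates zero (or identical with zero floor)
    pv = np.where(degenerate, 1.0, pv)
    reject, qv, _, _ = multipletests(pv.ravel(), alpha=fdr, method="fdr_bh")
    rows = []
    for t, typ in enumerate(MISMATCH_TYPES):
        for p in range(L):
            k = t * L + p
            rows.append((typ, p + 1, mean_a[t, p], mean_b[t, p], pv[t, p], qv[k], bool(reject[k])))
    return pd.DataFrame(
        rows, columns=["type", "position", "mean_a", "mean_b", "p_value", "q_value", "significant"]
    )


def biotype_distribution(assignments: pd.DataFrame, genes) -> tuple[dict[str, float], int]:
    """Fraction of assigned reads per RNA biotype, plus the unassigned count."""
    biotype_of = {g.gene_id: g.biotype for g in genes}
    assigned = assignments[assignments["gene_id"].notna() & (assignments["gene_id"] != AMBIGUOUS)]
    unassigned = len(assignments) - len(assigned)
    if len(assigned) == 0:
        return {}, unassigned
    counts = assigned["gene_id"].map(biotype_of).value_counts()
    return {b: c / len(assigned) for b, c in sorted(counts.items())}, unassigned
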