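"""Gene models, meta-transcript coordinates and transcript features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rna_dryqc.annotation import (
    GeneModel,
    MetaTranscript,
    TranscriptModel,
    build_meta_transcript,
    merge_intervals,
    read_gtf,
    transcript_features,
)


def gene(exons, strand="+", biotype="protein_coding", chrom="chr1", cds=None):
    tx = TranscriptModel("g.t1", exons=list(exons), cds=cds)
    return GeneModel("g", biotype, chrom, strand, transcripts=[tx])


class TestReadGtf:
    def test_coordinates_converted_to_zero_based_half_open(self, tiny_gtf):
        genes = read_gtf(tiny_gtf)
        ga = next(g for g in genes if g.gene_id == "GA")
        assert ga.transcripts[0].exons == [(100, 200), (300, 400)]
        assert ga.transcripts[0].cds == [(120, 200), (300, 360)]

    def test_polya_free_biotype_preserved(self, tiny_gtf):
        genes = read_gtf(tiny_gtf)
        gb = next(g for g in genes if g.gene_id == "GB")
        assert gb.biotype == "snoRNA"
        assert gb.strand == "-"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gtf(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gtf(path)

    def test_unknown_biotype_maps_to_other(self, tmp_path):
        path = tmp_path / "odd.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t"; gene_biotype "weird_class";\n'
        )
        (g,) = read_gtf(path)
        assert g.biotype == "other"


class TestMetaTranscript:
    def test_overlapping_exons_merge(self):
        meta = build_meta_transcript(gene([(100, 200), (150, 300)]))
        assert meta.blocks == [(100, 300)]
        assert meta.length == 200

    def test_disjoint_exons_stay_separate(self):
        meta = build_meta_transcript(gene([(0, 100), (200, 250)]))
        assert meta.blocks == [(0, 100), (200, 250)]
        assert meta.length == 150

    def test_single_exon_identity(self):
        meta = build_meta_transcript(gene([(0, 75)]))
        assert meta.blocks == [(0, 75)]
        assert meta.length == 75

    def test_merge_is_idempotent(self):
        merged = merge_intervals([(5, 30), (10, 40), (60, 80)])
        assert merge_intervals(merged) == merged

    def test_genomic_to_meta_plus_strand(self):
        meta = MetaTranscript("g", "chr1", "+", [(100, 200), (300, 400)])
        assert meta.genomic_to_meta("chr1", 305) == 105  # 100 exonic bases precede
        assert meta.genomic_to_meta("chr1", 250) is None  # intron
        assert meta.genomic_to_meta("chr2", 305) is None  # wrong chromosome

    def test_genomic_to_meta_minus_strand_five_prime_is_right_end(self):
        meta = MetaTranscript("g", "chr1", "-", [(100, 200)])
        assert meta.genomic_to_meta("chr1", 199) == 0
        assert meta.genomic_to_meta("chr1", 100) == 99

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_meta_map_is_bijection_onto_length(self, strand):
        blocks = [(10, 35), (50, 61), (70, 114)]
        meta = MetaTranscript("g", "chr1", strand, blocks)
        images = []
        for s, e in blocks:
            for pos in range(s, e):
                m = meta.genomic_to_meta("chr1", pos)
                assert m is not None and 0 <= m < meta.length
                assert meta.meta_to_genomic(m) == pos  # round trip
                images.append(m)
        assert sorted(images) == list(range(meta.length))

    @settings(max_examples=60, derandomize=True)
    @given(
        gaps=st.lists(st.tuples(st.integers(1, 50), st.integers(1, 80)), min_size=1, max_size=6),
        strand=st.sampled_from("+-"),
        data=st.data(),
    )
    def test_roundtrip_property_for_arbitrary_exon_structures(self, gaps, strand, data):
        """genomic_to_meta and meta_to_genomic invert each other everywhere."""
        pos = 5
        blocks = []
        for gap, width in gaps:
            pos += gap
            blocks.append((pos, pos + width))
            pos += width
        meta = MetaTranscript("g", "chr1", strand, blocks)
        m = data.draw(st.integers(0, meta.length - 1))
        g = meta.meta_to_genomic(m)
        assert meta.genomic_to_meta("chr1", g) == m

    def test_strand_symmetry(self):
        blocks = [(10, 35), (50, 61)]
        plus = MetaTranscript("g", "chr1", "+", blocks)
        minus = MetaTranscript("g", "chr1", "-", blocks)
        for pos in list(range(10, 35)) + list(range(50, 61)):
            mp = plus.genomic_to_meta("chr1", pos)
            mm = minus.genomic_to_meta("chr1", pos)
            assert mm == plus.length - 1 - mp

    def test_meta_interval_blocks_cross_junction(self):
        meta = MetaTranscript("g", "chr1", "+", [(100, 200), (300, 400)])
        assert meta.meta_interval_blocks(90, 110) == [(190, 200), (300, 310)]
        minus = MetaTranscript("g", "chr1", "-", [(100, 200), (300, 400)])
        # meta [0, 10) of a minus gene is the genomic right end
        assert minus.meta_interval_blocks(0, 10) == [(390, 400)]


class TestTranscriptFeatures:
    def test_gc_content(self):
        g = gene([(0, 6)])
        feats = transcript_features(g, {"chr1": "ATGCGC"})
        assert feats["transcript_length"] == 6
        assert feats["transcript_gc"] == 4
        assert feats["transcript_gc_pct"] == pytest.approx(66.6667, abs=1e-3)

    def test_all_at_sequence_is_zero_gc(self):
        feats = transcript_features(gene([(0, 8)]), {"chr1": "ATATATAT"})
        assert feats["transcript_gc_pct"] == 0.0

    def test_coding_region_lengths_are_additive(self):
        # 5'UTR "AA", CDS "ATGTAA", 3'UTR "GGGG"
        seq = "AAATGTAAGGGG"
        g = gene([(0, 12)], cds=[(2, 8)])
        feats = transcript_features(g, {"chr1": seq})
        assert (feats["utr5_length"], feats["cds_length"], feats["utr3_length"]) == (2, 6, 4)
        assert feats["cdna_length"] == 12
        assert feats["utr5_gc"] + feats["cds_gc"] + feats["utr3_gc"] == feats["cdna_gc"]

    def test_zero_length_region_reported_absent(self):
        g = gene([(0, 8)], cds=[(0, 6)])  # no 5'UTR
        feats = transcript_features(g, {"chr1": "ATGTAAGG"})
        assert feats["utr5_length"] is None
        assert feats["utr5_gc_pct"] is None

    def test_minus_strand_uses_reverse_complement(self):
        # genomic "AAAAAACC" reverse-complemented -> "GGTTTTTT"
        feats = transcript_features(gene([(0, 8)], strand="-"), {"chr1": "AAAAAACC"})
        assert feats["transcript_gc"] == 2

    def test_longest_transcript_breaks_ties_lexicographically(self):
        t1 = TranscriptModel("t2", exons=[(0, 50)])
        t2 = TranscriptModel("t1", exons=[(100, 150)])
        g = GeneModel("g", "lncRNA", "chr1", "+", transcripts=[t1, t2])
        assert g.longest_transcript().transcript_id == "t1"

    def test_missing_sequence_names_the_gene(self):
        with pytest.raises(KeyError, match="chr1"):
            transcript_features(gene([(0, 6)]), {})
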