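"""Library metrics, outlier rule, mismatch profiling and group comparison."""

import numpy as np
import pandas as pd
import pytest

from rna_dryqc.qc import (
    AlignedRead,
    SamTotals,
    biotype_distribution,
    compare_mismatch_profiles,
    deviation_from_median,
    library_metrics,
    mismatch_profile,
    read_sam,
)


def make_read(rid="r", chrom="chr1", start=0, seq="ACGT" * 19 + "ACG", dup=False, mism=()):
    return AlignedRead(
        read_id=rid, chromosome=chrom, blocks=((start, start + len(seq)),), strand="+",
        seq=seq, is_duplicate=dup, mismatches=tuple(mism),
    )


class TestReadSam:
    def test_unmapped_excluded_but_counted(self, tiny_sam):
        reads, totals = read_sam(tiny_sam)
        assert totals.total == 4
        assert totals.unmapped == 1
        assert totals.mapped == 3
        assert {r.read_id for r in reads} == {"r1", "r2", "r3"}

    def test_md_tag_semantics(self, tiny_sam):
        reads, _ = read_sam(tiny_sam)
        r1 = next(r for r in reads if r.read_id == "r1")
        # MD:Z:10A64 -> one mismatch at read position 11, reference base A
        assert r1.mismatches == ((11, "A", "C"),)

    def test_reverse_read_reported_in_cycle_orientation(self, tiny_sam):
        reads, _ = read_sam(tiny_sam)
        r2 = next(r for r in reads if r.read_id == "r2")
        assert r2.strand == "-"
        assert r2.seq == "C" * 75  # revcomp of the stored Gs

    def test_duplicate_flag_parsed(self, tiny_sam):
        reads, _ = read_sam(tiny_sam)
        assert next(r for r in reads if r.read_id == "r3").is_duplicate

    def test_empty_body_gives_empty_stream(self, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100\n")
        reads, totals = read_sam(p)
        assert reads == [] and totals.total == 0


class TestLibraryMetrics:
    def test_duplication_rate(self):
        reads = [make_read(rid=f"r{i}", dup=i < 4) for i in range(10)]
        m = library_metrics(reads, SamTotals(total=10, mapped=10, unique=10))
        assert m.duplication_rate == pytest.approx(0.4)

    def test_single_chromosome_fraction_is_one(self):
        reads = [make_read(rid=f"r{i}") for i in range(5)]
        m = library_metrics(reads, SamTotals(total=5, mapped=5, unique=5))
        assert m.chromosome_fractions == {"chr1": 1.0}

    def test_gc_histogram_bin(self):
        seq = "G" * 15 + "C" * 15 + "A" * 45  # 75-mer, 30 G/C -> 40%
        m = library_metrics([make_read(seq=seq)], SamTotals(total=1, mapped=1, unique=1))
        assert m.gc_histogram[40] == 1
        assert m.gc_histogram.sum() == 1

    def test_empty_sam_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            library_metrics([], SamTotals())


class TestDeviationFromMedian:
    def test_boundary_thirty_percent_flags_outlier(self):
        df = pd.DataFrame({"m": [10.0, 10.0, 13.0]}, index=["a", "b", "c"])
        dev, out = deviation_from_median(df)
        assert dev["m"].tolist() == pytest.approx([0.0, 0.0, 0.30])
        assert out.tolist() == [False, False, True]

    def test_identical_values_no_outliers(self):
        df = pd.DataFrame({"m": [5.0, 5.0, 5.0]})
        dev, out = deviation_from_median(df)
        assert (dev["m"] == 0).all() and not out.any()

    def test_reported_duplication_deviation_range(self):
        # deviations matching the -13.6%..+6.7% spread seen in real libraries
        df = pd.DataFrame({"dup": [8.64, 10.0, 10.67]})
        dev, out = deviation_from_median(df)
        assert dev["dup"].tolist() == pytest.approx([-0.136, 0.0, 0.067], abs=5e-4)
        assert not out.any()

    def test_zero_median_metric_skipped(self):
        df = pd.DataFrame({"z": [0.0, 0.0, 1.0], "ok": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="median is 0"):
            dev, _ = deviation_from_median(df)
        assert "z" not in dev.columns and "ok" in dev.columns

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            deviation_from_median(pd.DataFrame({"m": [1.0, 2.0]}))


class TestMismatchProfile:
    def test_no_mismatches_all_rates_zero(self):
        prof = mismatch_profile([make_read(rid=f"r{i}") for i in range(5)])
        assert prof.rates.sum() == 0

    def test_rate_is_count_over_reference_base_opportunity(self):
        # 10 reads with C at position 2; one has C>G there
        reads = [make_read(rid=f"r{i}", seq="AC" + "A" * 73) for i in range(9)]
        reads.append(make_read(rid="r9", seq="AG" + "A" * 73, mism=[(2, "C", "G")]))
        prof = mismatch_profile(reads)
        i = list(__import__("rna_dryqc.qc", fromlist=["MISMATCH_TYPES"]).MISMATCH_TYPES).index("C>G")
        assert prof.rates[i, 1] == pytest.approx(0.1)
        assert prof.denominators[i, 1] == 10

    def test_duplicates_excluded_from_denominators(self):
        reads = [make_read(rid="u", seq="C" * 75), make_read(rid="d", seq="C" * 75, dup=True)]
        prof = mismatch_profile(reads)
        assert prof.denominators.max() == 1

    def test_rates_invariant_to_read_order(self, small_experiment):
        lib = small_experiment["control_0"]
        a = mismatch_profile(lib.reads)
        b = mismatch_profile(list(reversed(lib.reads)))
        np.testing.assert_array_equal(a.rates, b.rates)


class TestCompareMismatchProfiles:
    def _profiles(self, experiment, group):
        return [mismatch_profile(experiment[f"{group}_{i}"].reads) for i in range(3)]

    def test_identical_groups_nothing_significant(self, small_experiment):
        a = self._profiles(small_experiment, "control")
        cmp = compare_mismatch_profiles(a, a)
        assert not cmp["significant"].any()
        assert (cmp["p_value"] == 1.0).all()

    def test_null_groups_nothing_significant(self, small_experiment):
        a = self._profiles(small_experiment, "control")
        b = self._profiles(small_experiment, "lyo")
        cmp = compare_mismatch_profiles(a, b)
        assert not cmp["significant"].any()

    def test_requires_two_samples_per_group(self, small_experiment):
        a = self._profiles(small_experiment, "control")
        with pytest.raises(ValueError):
            compare_mismatch_profiles(a[:1], a)


class TestBiotypeDistribution:
    def test_fractions_sum_to_one_with_unassigned(self, small_experiment, small_annotation, small_assignments):
        fractions, unassigned = biotype_distribution(
            small_assignments["control_0"], small_annotation.genes
        )
        assert fractions  # protein_coding etc. present
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert unassigned + sum(fractions.values()) * 0 >= 0

    def test_no_assigned_reads_gives_empty_distribution(self, small_annotation):
        df = pd.DataFrame({"read_id": ["r"], "gene_id": [None], "meta_pos": [-1], "duplicate": [False]})
        fractions, unassigned = biotype_distribution(df, small_annotation.genes)
        assert fractions == {} and unassigned == 1
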