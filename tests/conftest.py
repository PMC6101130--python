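import numpy as np
import pandas as pd
import pytest

from rna_dryqc.simulate import (
    GroupSpec,
    SimulationConfig,
    generate_annotation,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=25, depth=6_000)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_annotation):
    """Null 2x3 experiment: no degradation in either group."""
    return simulate_experiment(small_annotation, small_config)


@pytest.fixture(scope="session")
def small_index(small_annotation):
    return small_annotation.index()


@pytest.fixture(scope="session")
def small_assignments(small_experiment, small_index):
    return {sid: small_index.assign_reads(lib.reads) for sid, lib in small_experiment.items()}


@pytest.fixture()
def tiny_gtf(tmp_path):
    """Two genes: a 2-exon plus-strand coding gene and a minus-strand snoRNA."""
    lines = [
        # 1-based closed coordinates: exons 101-200 and 301-400 -> [100,200), [300,400)
        'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1"; gene_biotype "protein_coding";',
        'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1"; gene_biotype "protein_coding";',
        'chr1\ttest\tCDS\t121\t200\t.\t+\t0\tgene_id "GA"; transcript_id "GA.t1"; gene_biotype "protein_coding";',
        'chr1\ttest\tCDS\t301\t360\t.\t+\t0\tgene_id "GA"; transcript_id "GA.t1"; gene_biotype "protein_coding";',
        'chr2\ttest\texon\t51\t150\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1"; gene_biotype "snoRNA";',
    ]
    path = tmp_path / "tiny.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def tiny_sam(tmp_path):
    """Handcrafted SAM exercising flags, MD tags and both strands."""
    body = [
        "@HD\tVN:1.6\tSO:coordinate",
        "@SQ\tSN:chr1\tLN:1000",
        # forward read, one mismatch at read position 11, reference base A
        "r1\t0\tchr1\t101\t50\t75M\t*\t0\t0\t" + "C" * 75 + "\t*\tNH:i:1\tNM:i:1\tMD:Z:10A64",
        # reverse-strand perfect read
        "r2\t16\tchr1\t201\t50\t75M\t*\t0\t0\t" + "G" * 75 + "\t*\tNH:i:1\tNM:i:0\tMD:Z:75",
        # duplicate-flagged forward read
        "r3\t1024\tchr1\t301\t50\t75M\t*\t0\t0\t" + "A" * 75 + "\t*\tNH:i:1\tNM:i:0\tMD:Z:75",
        # unmapped record
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\t" + "T" * 75 + "\t*",
    ]
    path = tmp_path / "tiny.sam"
    path.write_text("\n".join(body) + "\n")
    return path
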