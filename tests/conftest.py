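"""Shared fixtures: a hand-written toy annotation and a session-scoped
simulated dataset (29-member family in three groups of 9/15/5)."""

import numpy as np
import pytest

from snoquant import (
    FamilySpec,
    GenomicInterval,
    NcRNALocus,
    make_genome,
    member_rpkms_from_group,
    simulate_reads,
)

# loci below are carved out of the 81-nt block spanning positions 10..91
TOY_CHROM_SEQ = "T" * 10 + ("ACGT" * 21)[:81] + "G" * 10


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(f">chrToy\n{TOY_CHROM_SEQ}\n")
    return path


@pytest.fixture
def toy_annotation(tmp_path):
    """1-based inclusive coordinates, as the annotation format specifies."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "locus_id\tname\tchrom\tstart\tend\tstrand\trna_class\tcluster\n"
        "L1\tSNO1\tchrToy\t11\t91\t+\tCD_box\tSNO1\n"
        "L2\tSNO2\tchrToy\t11\t91\t-\tCD_box\tSNO2\n"
    )
    return path


def locus(locus_id, chrom, start, end, strand="+", rna_class="CD_box", seq=None):
    """Convenience constructor with an arbitrary valid sequence."""
    if seq is None:
        seq = ("ACGT" * ((end - start) // 4 + 1))[: end - start]
    return NcRNALocus(
        locus_id=locus_id,
        name=locus_id,
        interval=GenomicInterval(chrom, start, end, strand),
        rna_class=rna_class,
        sequence=seq,
    )


#: the three-group family structure and hypothalamus-pattern group RPKMs
GROUP_SIZES = [9, 15, 5]
GROUP_RPKMS = {"I": 14439.0, "II": 635.0, "III": 242.0}
SIM_SEED = 7
SIM_ALIGNED_TOTAL = 100_000


@pytest.fixture(scope="session")
def family_genome():
    return make_genome(
        [FamilySpec("FAM", 29, group_sizes=GROUP_SIZES)],
        n_mrnas=3,
        overlap_pairs=1,
        seed=SIM_SEED,
    )


@pytest.fixture(scope="session")
def family_cluster(family_genome):
    return family_genome.cluster("FAM")


@pytest.fixture(scope="session")
def simulated(family_genome, family_cluster):
    expression = member_rpkms_from_group(family_cluster, GROUP_RPKMS)
    for l in family_genome.loci:
        if l.rna_class == "mRNA":
            expression[l.locus_id] = 200.0
    return simulate_reads(
        family_genome,
        expression,
        n_aligned_total=SIM_ALIGNED_TOTAL,
        seed=SIM_SEED + 1,
    )


@pytest.fixture(scope="session")
def simulated_reads(simulated):
    return simulated.aligned_reads()
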