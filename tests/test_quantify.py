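"""Counting rules, RPKM/Poisson normalization, enrichment tallies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snoquant import (
    AlignedRead,
    ExpressionRecord,
    GenomicInterval,
    NcRNACluster,
    count_cluster,
    count_groups,
    count_members,
    count_mrna,
    count_simple_features,
    enrichment_tally,
    rpkm_normalize,
    trim_reads,
)
from snoquant.model import Group

from conftest import locus


def read(read_id, *placements, length=28, sample="s"):
    return AlignedRead(
        read_id=read_id,
        length=length,
        alignments=[
            GenomicInterval(c, start, start + length, strand)
            for c, start, strand in placements
        ],
        sample=sample,
    )


# ---------------------------------------------------------------------------
# trimming

class TestTrimReads:
    @pytest.mark.parametrize("raw_length", [36, 50])
    def test_long_reads_keep_first_28_nt(self, raw_length):
        seq = "ACGT" * 13  # 52 nt
        result = trim_reads([("r1", seq[:raw_length])], target_length=28)
        assert result.reads == [("r1", seq[:28])]
        assert result.n_dropped == 0

    def test_short_reads_dropped_and_counted(self):
        result = trim_reads([("r1", "A" * 20), ("r2", "C" * 28)])
        assert [r[0] for r in result.reads] == ["r2"]
        assert result.n_dropped == 1

    def test_quality_trimmed_alongside_sequence(self):
        result = trim_reads([("r1", "A" * 36, "I" * 36)])
        assert result.reads == [("r1", "A" * 28, "I" * 28)]


# ---------------------------------------------------------------------------
# mRNA counting

class TestCountMrna:
    def setup_method(self):
        self.gene_a = locus("A", "chr1", 100, 600, "+", rna_class="mRNA")
        self.gene_b = locus("B", "chr1", 540, 1040, "+", rna_class="mRNA")
        self.far = locus("C", "chr2", 0, 500, "-", rna_class="mRNA")
        self.genes = [self.gene_a, self.gene_b, self.far]

    def test_sense_read_in_single_gene_counts_once(self):
        counts = count_mrna([read("r1", ("chr1", 200, "+"))], self.genes)
        assert counts == {"A": 1, "B": 0, "C": 0}

    def test_read_overlapping_two_genes_counts_for_neither(self):
        # placement inside the A/B overlap (540..572 within both spans)
        counts = count_mrna([read("r1", ("chr1", 550, "+"))], self.genes)
        assert counts == {"A": 0, "B": 0, "C": 0}

    def test_antisense_read_not_counted(self):
        counts = count_mrna([read("r1", ("chr1", 200, "-"))], self.genes)
        assert counts == {"A": 0, "B": 0, "C": 0}

    def test_multi_placement_across_genes_disqualifies(self):
        r = read("r1", ("chr1", 200, "+"), ("chr2", 100, "-"))
        assert count_mrna([r], self.genes) == {"A": 0, "B": 0, "C": 0}

    def test_edge_overlap_of_one_nt_counts(self):
        counts = count_mrna([read("r1", ("chr1", 73, "+"))], self.genes)
        assert counts["A"] == 1  # read spans 73..101, one nt inside A


# ---------------------------------------------------------------------------
# cluster / group counting

@pytest.fixture
def three_group_cluster():
    members = []
    # groups I (2 members), II (2), III (1), 81 nt each, interleaved gaps
    for i in range(5):
        members.append(locus(f"m{i+1}", "chr1", 1000 * (i + 1), 1000 * (i + 1) + 81))
    groups = [
        Group("I", ("m1", "m2")),
        Group("II", ("m3", "m4")),
        Group("III", ("m5",)),
    ]
    return NcRNACluster("HB", members, effective_length=81.0, groups=groups)


class TestCountCluster:
    def test_multi_member_placement_counts_once(self, three_group_cluster):
        r = read("r1", ("chr1", 1010, "+"), ("chr1", 2010, "+"))
        assert count_cluster([r], three_group_cluster) == 1

    def test_outside_placement_lenient_vs_strict(self, three_group_cluster):
        r = read("r1", ("chr1", 1010, "+"), ("chr1", 500000, "+"))
        assert count_cluster([r], three_group_cluster, unique_mode="lenient") == 1
        assert count_cluster([r], three_group_cluster, unique_mode="strict") == 0

    def test_no_overlap_counts_zero(self, three_group_cluster):
        assert count_cluster([read("r1", ("chr1", 100, "+"))], three_group_cluster) == 0

    def test_antisense_placement_not_counted(self, three_group_cluster):
        assert count_cluster([read("r1", ("chr1", 1010, "-"))], three_group_cluster) == 0


class TestCountGroups:
    def test_within_group_multimapper_assigned_to_its_group(self, three_group_cluster):
        r = read("r1", ("chr1", 1010, "+"), ("chr1", 2010, "+"))  # m1+m2, both I
        result = count_groups([r], three_group_cluster)
        assert result.counts == {"I": 1, "II": 0, "III": 0}
        assert result.ambiguous == 0

    def test_cross_group_read_goes_to_ambiguous_bin(self, three_group_cluster):
        r = read("r1", ("chr1", 1010, "+"), ("chr1", 3010, "+"))  # m1 (I) + m3 (II)
        result = count_groups([r], three_group_cluster)
        assert result.counts == {"I": 0, "II": 0, "III": 0}
        assert result.ambiguous == 1

    def test_single_group_reads_conserve_cluster_count(self, three_group_cluster):
        reads = [read(f"r{i}", ("chr1", 1000 + i, "+")) for i in range(10)]
        result = count_groups(reads, three_group_cluster)
        assert result.counts["I"] == count_cluster(reads, three_group_cluster) == 10
        assert result.counts["II"] == result.counts["III"] == 0

    def test_missing_groups_is_fatal(self, three_group_cluster):
        bare = NcRNACluster("HB", three_group_cluster.members, 81.0)
        with pytest.raises(ValueError, match="group"):
            count_groups([], bare)

    def test_conservation_on_simulated_data(
        self, simulated_reads, family_cluster, simulated
    ):
        total = count_cluster(simulated_reads, family_cluster)
        result = count_groups(simulated_reads, family_cluster)
        assert result.total == total
        assert sum(result.counts.values()) + result.ambiguous == total

    def test_strand_flip_zeroes_all_sense_counts(self, three_group_cluster):
        reads = [read(f"r{i}", ("chr1", 1000 + i, "+")) for i in range(5)]
        flipped = [
            read(r.read_id, *[(a.chrom, a.start, "-") for a in r.alignments])
            for r in reads
        ]
        assert count_cluster(flipped, three_group_cluster) == 0
        result = count_groups(flipped, three_group_cluster)
        assert result.total == 0


class TestCountMembers:
    def test_member_exclusive_reads_only(self, three_group_cluster):
        exclusive = read("r1", ("chr1", 5010, "+"))          # m5 only
        shared = read("r2", ("chr1", 1010, "+"), ("chr1", 2010, "+"))  # m1+m2
        result = count_members([exclusive, shared], three_group_cluster)
        assert result.counts["m5"] == 1
        assert result.counts["m1"] == result.counts["m2"] == 0
        assert result.ambiguous == 1


# ---------------------------------------------------------------------------
# naive-oracle equivalence

def naive_counts(reads, features, mode):
    """O(reads x features) re-implementation with inline overlap arithmetic."""
    counts = {f.locus_id: 0 for f in features}
    for r in reads:
        touched, sense = set(), set()
        for a in r.alignments:
            for f in features:
                iv = f.interval
                if (
                    a.chrom == iv.chrom
                    and a.start < iv.end
                    and iv.start < a.end
                ):
                    touched.add(f.locus_id)
                    if a.strand == iv.strand:
                        sense.add(f.locus_id)
        if mode == "mrna":
            if len(touched) == 1 and touched <= sense:
                counts[next(iter(touched))] += 1
        else:  # unique overlap per feature
            for fid in sense:
                counts[fid] += 1
    return counts


def test_counting_matches_naive_double_loop():
    rng = np.random.default_rng(17)
    features = [
        locus(f"f{i}", f"chr{rng.integers(1, 4)}", int(s), int(s) + 81,
              "+" if rng.random() < 0.5 else "-")
        for i, s in enumerate(rng.integers(0, 50_000, size=30) * 1)
    ]
    reads = []
    for i in range(2000):
        n_placements = 1 + (rng.random() < 0.3)
        placements = [
            (f"chr{rng.integers(1, 4)}", int(rng.integers(0, 50_050)),
             "+" if rng.random() < 0.5 else "-")
            for _ in range(n_placements)
        ]
        reads.append(read(f"r{i}", *placements))

    assert count_mrna(reads, features) == naive_counts(reads, features, "mrna")

    cluster = NcRNACluster("C", features, effective_length=81.0)
    naive_cluster = sum(
        1
        for r in reads
        if any(
            a.chrom == f.interval.chrom
            and a.start < f.interval.end
            and f.interval.start < a.end
            and a.strand == f.interval.strand
            for a in r.alignments
            for f in features
        )
    )
    assert count_cluster(reads, cluster) == naive_cluster


# ---------------------------------------------------------------------------
# normalization

class TestRpkmNormalize:
    def test_published_scale_worked_example(self):
        rpkm, _ = rpkm_normalize(104_744, 26_200_000, 81)
        assert round(rpkm, -3) == 49_000  # two significant figures

    def test_zero_count_gives_zero_rpkm_and_sigma(self):
        assert rpkm_normalize(0, 1_000_000, 81) == (0.0, 0.0)

    def test_unit_definition(self):
        assert rpkm_normalize(100, 1_000_000, 1000) == (100.0, 10.0)

    @pytest.mark.parametrize(
        "count,total,length",
        [(1, 0, 81), (1, 100, 0), (-1, 100, 81)],
    )
    def test_invalid_inputs_fatal(self, count, total, length):
        with pytest.raises(ValueError):
            rpkm_normalize(count, total, length)

    @given(
        st.integers(0, 10**6),
        st.integers(1, 10**8),
        st.integers(1, 10**5),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_linearity_and_sigma_contract(self, count, total, length):
        rpkm, sigma = rpkm_normalize(count, total, length)
        rpkm2, _ = rpkm_normalize(2 * count, total, length)
        assert rpkm2 == pytest.approx(2 * rpkm)
        half, _ = rpkm_normalize(count, 2 * total, length)
        assert half == pytest.approx(rpkm / 2)
        assert sigma == pytest.approx(
            math.sqrt(count) / (length / 1000) / (total / 1e6)
        )


# ---------------------------------------------------------------------------
# simple features and enrichment

class TestCountSimpleFeatures:
    def test_trna_mode_full_rpkm(self):
        trna = locus("tRNA1", "chr1", 1000, 1072, "+", rna_class="tRNA")
        reads = [read(f"r{i}", ("chr1", 1010, "+")) for i in range(36)]
        (rec,) = count_simple_features(reads, [trna], aligned_total=1_000_000)
        assert rec.count == 36
        assert rec.rpkm == pytest.approx(36 / 0.072)  # 500

    def test_lincrna_mode_is_per_million_only(self):
        linc = locus("linc1", "chr1", 0, 40_000, "+", rna_class="lincRNA")
        reads = [read(f"r{i}", ("chr1", 100 + 30 * i, "+")) for i in range(355)]
        (rec,) = count_simple_features(
            reads, [linc], aligned_total=1_000_000, length_normalize=False
        )
        assert rec.rpkm == pytest.approx(355.0)  # RPM, independent of length

    def test_zero_overlap_feature_is_zero(self):
        far = locus("t", "chr9", 0, 72, "+", rna_class="tRNA")
        (rec,) = count_simple_features(
            [read("r1", ("chr1", 5, "+"))], [far], aligned_total=1000
        )
        assert rec.count == 0 and rec.rpkm == 0.0


def make_record(fid, sample, rpkm):
    count = max(int(rpkm), 0)
    return ExpressionRecord(
        feature_id=fid, scope="cluster", sample=sample, count=count,
        rpkm=rpkm, rpkm_sigma=math.sqrt(count), effective_length=81.0,
        aligned_total=10**6,
    )


class TestEnrichmentTally:
    def test_argmax_tissue_assignment(self):
        records = [
            make_record("HBI-6", "testes", 166.0),
            make_record("HBI-6", "hypothalamus", 13.0),
        ]
        result = enrichment_tally(records, {"HBI-6": "HACA_box"})
        row = result.features.iloc[0]
        assert row.max_sample == "testes" and not row.tie
        assert result.tally.loc["HACA_box", "testes"] == 1

    def test_features_at_or_below_threshold_excluded(self):
        records = [make_record("X", "lung", 10.0), make_record("X", "heart", 3.0)]
        result = enrichment_tally(records, {"X": "CD_box"})
        assert result.features.empty

    def test_matches_hand_enumerated_argmax_counts(self):
        rng = np.random.default_rng(23)
        samples = ["t1", "t2", "t3"]
        classes = {f"f{i}": ("CD_box" if i % 2 else "HACA_box") for i in range(6)}
        table = {f: {s: float(rng.integers(0, 200)) for s in samples} for f in classes}
        records = [
            make_record(f, s, v) for f, by_s in table.items() for s, v in by_s.items()
        ]
        result = enrichment_tally(records, classes, threshold=10.0, sample_order=samples)
        for f, by_s in table.items():
            best = max(by_s.values())
            if best <= 10.0:
                assert f not in set(result.features.feature_id)
                continue
            expected = [s for s in samples if by_s[s] == best][0]
            row = result.features.set_index("feature_id").loc[f]
            assert row.max_sample == expected

    def test_tie_flagged_not_hidden(self):
        records = [make_record("X", "a", 50.0), make_record("X", "b", 50.0)]
        result = enrichment_tally(records, {"X": "CD_box"}, sample_order=["a", "b"])
        row = result.features.iloc[0]
        assert row.tie and row.max_sample == "a"


def test_expression_record_rejects_count_above_total():
    with pytest.raises(ValueError, match="exceeds"):
        ExpressionRecord(
            feature_id="x", scope="cluster", sample="s", count=11,
            rpkm=1.0, rpkm_sigma=1.0, effective_length=81.0, aligned_total=10,
        )
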