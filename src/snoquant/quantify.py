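"""Read counting at mRNA/cluster/group/member scope and RPKM normalization.

Counting rules
--------------
* A read counts for an mRNA only when the set of genes overlapped by *any* of
  its placements has size exactly one and at least one placement overlaps
  that gene on the gene's strand (correct genomic orientation).
* A read counts for a cluster at most once ("unique reads"), no matter how
  many member copies it hits.  In the default lenient mode a placement
  outside the cluster does not disqualify the read (the cluster merged all
  related locations precisely so such reads stay countable); strict mode
  drops reads with any non-member placement.
* Group counting assigns a read to group g only when every member-overlapping
  placement falls in g; reads spanning two groups land in an explicit
  ambiguous bin, never silently dropped, so that
  sum(group counts) + ambiguous == cluster count holds on every input.

Normalization is RPKM — reads per 1000 nt of feature length per million
aligned reads — with a Poisson counting uncertainty: sigma(count) =
sqrt(count), pushed through the identical normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .model import AlignedRead, ExpressionRecord, GenomicInterval, NcRNACluster

DEFAULT_READ_LENGTH = 28

UNIQUE_MODES = ("lenient", "strict")


# ---------------------------------------------------------------------------
# read trimming

@dataclass
class TrimResult:
    """Trimmed reads plus a drop counter for reads shorter than the target."""

    reads: list
    n_dropped: int


def trim_reads(reads, target_length: int = DEFAULT_READ_LENGTH) -> TrimResult:
    """Truncate every read from the 3' end to exactly *target_length* nt.

    Reads are (read_id, sequence) or (read_id, sequence, quality) tuples.
    Trimming all reads to one common length avoids aligning sequenced
    amplification primer and makes counts comparable across runs of
    different raw lengths.  Reads shorter than the target are dropped and
    counted, not padded.
    """
    kept, dropped = [], 0
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        qual = rec[2] if len(rec) > 2 else None
        if len(seq) < target_length:
            dropped += 1
            continue
        if qual is None:
            kept.append((read_id, seq[:target_length]))
        else:
            kept.append((read_id, seq[:target_length], qual[:target_length]))
    return TrimResult(reads=kept, n_dropped=dropped)


def trim_fastq(in_path, out_path, target_length: int = DEFAULT_READ_LENGTH) -> TrimResult:
    """File-level :func:`trim_reads`; returns counts, not sequences."""
    from Bio import SeqIO

    n_kept = n_dropped = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(in_path), "fastq"):
            if len(rec.seq) < target_length:
                n_dropped += 1
                continue
            SeqIO.write(rec[:target_length], out, "fastq")
            n_kept += 1
    return TrimResult(reads=[], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# interval index

class FeatureIndex:
    """Per-chromosome interval tree over (feature_id, interval) pairs."""

    def __init__(self, features: Mapping[str, GenomicInterval]):
        self._trees: dict = {}
        for fid, iv in features.items():
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (fid, iv)
            )

    @classmethod
    def from_loci(cls, loci) -> "FeatureIndex":
        return cls({l.locus_id: l.interval for l in loci})

    def overlapping(self, alignment: GenomicInterval, stranded: bool = False):
        """(feature_id, interval) pairs overlapping *alignment* by >= 1 nt."""
        tree = self._trees.get(alignment.chrom)
        if tree is None:
            return []
        hits = [
            hit.data
            for hit in tree.overlap(alignment.start, alignment.end)
        ]
        if stranded:
            hits = [(fid, iv) for fid, iv in hits if iv.strand == alignment.strand]
        return hits


# ---------------------------------------------------------------------------
# counting

def count_mrna(reads: Iterable[AlignedRead], transcripts) -> dict:
    """Single-gene, orientation-correct read counts per transcript.

    Reads whose placements touch more than one gene (e.g. overlapping gene
    pairs) count for neither; antisense-only reads count for nothing.
    """
    index = FeatureIndex.from_loci(transcripts)
    counts = {t.locus_id: 0 for t in transcripts}
    for read in reads:
        touched: set = set()
        sense: set = set()
        for aln in read.alignments:
            for fid, iv in index.overlapping(aln):
                touched.add(fid)
                if iv.strand == aln.strand:
                    sense.add(fid)
        if len(touched) == 1:
            (gene,) = touched
            if gene in sense:
                counts[gene] += 1
    return counts


def _member_hits(read: AlignedRead, index: FeatureIndex):
    """Member ids hit on the correct strand, and whether any placement
    misses the cluster entirely."""
    hit_members: set = set()
    any_outside = False
    for aln in read.alignments:
        hits = index.overlapping(aln)
        if not hits:
            any_outside = True
            continue
        for fid, iv in hits:
            if iv.strand == aln.strand:
                hit_members.add(fid)
    return hit_members, any_outside


def count_cluster(
    reads: Iterable[AlignedRead],
    cluster: NcRNACluster,
    unique_mode: str = "lenient",
) -> int:
    """Unique reads mapping to any member locus on the correct strand."""
    if unique_mode not in UNIQUE_MODES:
        raise ValueError(f"unique_mode must be one of {UNIQUE_MODES}")
    index = FeatureIndex.from_loci(cluster.members)
    count = 0
    for read in reads:
        hit, outside = _member_hits(read, index)
        if hit and not (unique_mode == "strict" and outside):
            count += 1
    return count


@dataclass
class GroupCounts:
    """Per-group unique-read counts plus the cross-group ambiguous bin."""

    counts: dict
    ambiguous: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.ambiguous


def count_groups(
    reads: Iterable[AlignedRead],
    cluster: NcRNACluster,
    unique_mode: str = "lenient",
) -> GroupCounts:
    """Unique reads aligning only to members of an individual group.

    Satisfies exact conservation with :func:`count_cluster`:
    ``sum(counts) + ambiguous == count_cluster(reads, cluster)``.
    """
    if cluster.groups is None:
        raise ValueError(
            f"cluster {cluster.cluster_id} has no group partition; run "
            "partition_groups first"
        )
    if unique_mode not in UNIQUE_MODES:
        raise ValueError(f"unique_mode must be one of {UNIQUE_MODES}")
    index = FeatureIndex.from_loci(cluster.members)
    group_of = {
        mid: g.label for g in cluster.groups for mid in g.member_ids
    }
    counts = {g.label: 0 for g in cluster.groups}
    ambiguous = 0
    for read in reads:
        hit, outside = _member_hits(read, index)
        if not hit or (unique_mode == "strict" and outside):
            continue
        groups_hit = {group_of[mid] for mid in hit}
        if len(groups_hit) == 1:
            counts[groups_hit.pop()] += 1
        else:
            ambiguous += 1
    return GroupCounts(counts=counts, ambiguous=ambiguous)


def count_members(
    reads: Iterable[AlignedRead],
    cluster: NcRNACluster,
    unique_mode: str = "lenient",
) -> GroupCounts:
    """Member-exclusive counting: each member treated as its own group.

    A read counts for member m only when m is the sole member it hits; reads
    ambiguous between members land in the ambiguous bin.  This is how
    individual members of a discriminable cluster (every pairwise shared
    28-mer count zero) are quantified.
    """
    from .model import Group

    singleton = NcRNACluster(
        cluster_id=cluster.cluster_id,
        members=cluster.members,
        effective_length=cluster.effective_length,
        groups=[Group(label=mid, member_ids=(mid,)) for mid in cluster.member_ids],
    )
    result = count_groups(reads, singleton, unique_mode=unique_mode)
    return result


# ---------------------------------------------------------------------------
# normalization

def rpkm_normalize(count: int, aligned_total: int, effective_length: float):
    """RPKM and its Poisson uncertainty.

    rpkm       = count      / (effective_length/1000) / (aligned_total/1e6)
    rpkm_sigma = sqrt(count) / (effective_length/1000) / (aligned_total/1e6)
    """
    if aligned_total <= 0:
        raise ValueError("aligned_total must be > 0")
    if effective_length <= 0:
        raise ValueError("effective_length must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    scale = 1.0 / (effective_length / 1000.0) / (aligned_total / 1e6)
    return count * scale, math.sqrt(count) * scale


# ---------------------------------------------------------------------------
# simple overlap features (tRNA / lincRNA style)

def count_simple_features(
    reads: Iterable[AlignedRead],
    features,
    aligned_total: int,
    sample: str = "",
    length_normalize: bool = True,
) -> list:
    """Unique-read overlap counts per feature, RPKM- or RPM-normalized.

    With ``length_normalize`` (the tRNA convention) values are full RPKM;
    without it (the lincRNA convention) values are reads per million aligned
    only — the rpkm field then holds RPM and effective_length is recorded as
    1000 so the record's internal algebra still closes.
    """
    index = FeatureIndex.from_loci(features)
    counts = {f.locus_id: 0 for f in features}
    for read in reads:
        seen: set = set()
        for aln in read.alignments:
            for fid, iv in index.overlapping(aln):
                if iv.strand == aln.strand:
                    seen.add(fid)
        for fid in seen:
            counts[fid] += 1
    records = []
    for f in features:
        eff_len = float(f.length) if length_normalize else 1000.0
        records.append(
            ExpressionRecord.from_count(
                feature_id=f.locus_id,
                scope="region",
                sample=sample,
                count=counts[f.locus_id],
                effective_length=eff_len,
                aligned_total=aligned_total,
            )
        )
    return records


# ---------------------------------------------------------------------------
# tissue-enrichment tally

@dataclass
class EnrichmentTally:
    """Per-feature argmax table and per-class/max-sample counts."""

    features: pd.DataFrame  # feature_id, rna_class, max_sample, max_rpkm, tie
    tally: pd.DataFrame     # index rna_class, columns samples, values counts


def enrichment_tally(
    records: Iterable[ExpressionRecord],
    class_of: Mapping[str, str],
    threshold: float = 10.0,
    sample_order=None,
) -> EnrichmentTally:
    """Which tissue each above-threshold feature peaks in, tallied per class.

    A feature qualifies when its maximum RPKM over samples exceeds
    *threshold*; its max-tissue is the argmax sample.  Ties are broken by the
    fixed *sample_order* (default: order of first appearance) and flagged
    rather than hidden.
    """
    per_feature: dict = {}
    seen_samples: list = []
    for rec in records:
        per_feature.setdefault(rec.feature_id, {})[rec.sample] = rec.rpkm
        if rec.sample not in seen_samples:
            seen_samples.append(rec.sample)
    order = list(sample_order) if sample_order is not None else seen_samples

    rows = []
    for fid, by_sample in per_feature.items():
        max_rpkm = max(by_sample.values())
        if max_rpkm <= threshold:
            continue
        argmax = [s for s in order if by_sample.get(s) == max_rpkm]
        rows.append(
            {
                "feature_id": fid,
                "rna_class": class_of[fid],
                "max_sample": argmax[0],
                "max_rpkm": max_rpkm,
                "tie": len(argmax) > 1,
            }
        )
    features = pd.DataFrame(
        rows, columns=["feature_id", "rna_class", "max_sample", "max_rpkm", "tie"]
    )
    if features.empty:
        tally = pd.DataFrame()
    else:
        tally = (
            features.groupby(["rna_class", "max_sample"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=[s for s in order if s in set(features.max_sample)])
        )
    return EnrichmentTally(features=features, tally=tally)


# ---------------------------------------------------------------------------
# output

def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "scope": r.scope,
                "sample": r.sample,
                "count": r.count,
                "rpkm": r.rpkm,
                "rpkm_sigma": r.rpkm_sigma,
                "effective_length": r.effective_length,
                "aligned_total": r.aligned_total,
            }
            for r in records
        ]
    )


def write_expression_tsv(records, path) -> None:
    expression_table(records).to_csv(path, sep="\t", index=False)
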