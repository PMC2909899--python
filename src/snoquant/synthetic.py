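"""Synthetic multi-copy ncRNA genomes, stranded read simulation, and a toy
exact-match aligner.

The generator emulates the data regime the pipeline is built for:

* multi-copy snoRNA families whose members fall into groups — members within
  a group share identical 28-mers (reads cross-map within the group) while
  members of different groups share none (reads never cross groups);
* single-copy mRNAs, including overlapping gene pairs that exercise the
  single-gene counting filter;
* stranded fixed-length reads drawn per feature with Poisson count noise at
  specified true RPKM levels, uniform start positions, an optional antisense
  fraction, and a fraction of unalignable reads;
* an exact-match aligner that reports every genomic placement of a read on
  either strand, emitting multi-line SAM — the clean regime in which
  group-count conservation is exactly provable.

Group structure is produced by mutating a shared family ancestor separately
per group and redrawing (bounded retries) until the similarity module itself
certifies zero cross-group 28-mer sharing and one connected component per
group.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import samio
from .annotation import build_clusters, write_annotation
from .model import GenomicInterval, NcRNACluster, NcRNALocus, reverse_complement
from .similarity import kmer_similarity, partition_groups

BASES = np.array(list("ACGT"))

DEFAULT_MEMBER_LENGTH = 81  # one snoRNA copy
DEFAULT_READ_LENGTH = 28


@dataclass
class FamilySpec:
    """Blueprint for one multi-copy family.

    ``within_group_divergence`` substitutions separate each member from its
    group ancestor (small: members still share most 28-mers).
    ``between_group_divergence`` substitutions separate each group ancestor
    from the family ancestor; the default member_length // 3 places a
    mismatch roughly every third base so that, with high probability, every
    28-mer window differs between groups — validated, not assumed.
    ``strand`` is the placement rule: '+', '-', or 'alternate'.
    """

    family_id: str
    n_members: int
    member_length: int = DEFAULT_MEMBER_LENGTH
    group_sizes: list | None = None
    within_group_divergence: int = 2
    between_group_divergence: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            self.group_sizes = [self.n_members]
        if sum(self.group_sizes) != self.n_members:
            raise ValueError(
                f"family {self.family_id}: group_sizes {self.group_sizes} "
                f"do not sum to n_members {self.n_members}"
            )
        if self.between_group_divergence is None:
            self.between_group_divergence = self.member_length // 3
        if self.strand not in ("+", "-", "alternate"):
            raise ValueError(f"strand rule must be '+', '-' or 'alternate'")


def _random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng, seq: str, n_subs: int) -> str:
    """Substitute *n_subs* distinct positions, each to a different base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def _draw_family(rng, spec: FamilySpec, k: int, max_tries: int = 50):
    """Member sense sequences satisfying the group structure, or raise."""
    for _ in range(max_tries):
        ancestor = _random_seq(rng, spec.member_length)
        seqs = []
        for size in spec.group_sizes:
            group_anc = _mutate(rng, ancestor, spec.between_group_divergence)
            seqs.extend(
                _mutate(rng, group_anc, spec.within_group_divergence)
                for _ in range(size)
            )
        probes = [
            NcRNALocus(
                locus_id=f"probe{i}",
                name=f"probe{i}",
                interval=GenomicInterval("probe", i * 1000, i * 1000 + len(s), "+"),
                rna_class="CD_box",
                sequence=s,
            )
            for i, s in enumerate(seqs)
        ]
        groups = partition_groups(kmer_similarity(probes, k=k), threshold=1)
        if [len(g.member_ids) for g in groups] == list(spec.group_sizes):
            return seqs
    raise RuntimeError(
        f"family {spec.family_id}: could not realize group sizes "
        f"{spec.group_sizes} with zero cross-group {k}-mer sharing in "
        f"{max_tries} tries; raise between_group_divergence"
    )


@dataclass
class SyntheticGenome:
    """Genome + annotation + relatedness mapping + pre-built clusters."""

    genome: dict
    loci: list
    relatedness: dict
    clusters: list
    seed: int

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def cluster(self, cluster_id: str) -> NcRNACluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.tsv",
            "relatedness": outdir / "relatedness.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_annotation(self.loci, paths["annotation"], relatedness=self.relatedness)
        pd.DataFrame(
            sorted(self.relatedness.items()), columns=["name", "cluster_name"]
        ).to_csv(paths["relatedness"], sep="\t", index=False)
        return paths


def make_genome(
    specs,
    n_mrnas: int = 4,
    overlap_pairs: int = 1,
    seed: int = 0,
    mrna_length: int = 500,
    overlap_nt: int = 60,
    spacer: int = 200,
    chrom: str = "chrS",
    k: int = DEFAULT_READ_LENGTH,
) -> SyntheticGenome:
    """Assemble a toy chromosome holding the requested families and mRNAs.

    Deterministic given *seed*.  Each emitted family is validated through the
    similarity module: partitioning its members at threshold 1 must reproduce
    the requested group sizes exactly (zero cross-group k-mer sharing).
    Overlapping mRNA pairs share ``overlap_nt`` nt on the same strand so
    reads from the shared span hit two genes.
    """
    rng = np.random.default_rng(seed)
    chunks: list = []
    pos = 0
    loci: list = []
    relatedness: dict = {}

    def emit(segment: str) -> int:
        nonlocal pos
        chunks.append(segment)
        start = pos
        pos += len(segment)
        return start

    def emit_spacer() -> None:
        emit(_random_seq(rng, spacer))

    for spec in specs:
        seqs = _draw_family(rng, spec, k=k)
        for i, sense in enumerate(seqs, start=1):
            if spec.strand == "alternate":
                strand = "+" if i % 2 else "-"
            else:
                strand = spec.strand
            emit_spacer()
            start = emit(sense if strand == "+" else reverse_complement(sense))
            name = f"{spec.family_id}-{i}"
            loci.append(
                NcRNALocus(
                    locus_id=name,
                    name=name,
                    interval=GenomicInterval(chrom, start, start + len(sense), strand),
                    rna_class="CD_box",
                    sequence=sense,
                )
            )
            relatedness[name] = spec.family_id

    for i in range(1, n_mrnas + 1):
        emit_spacer()
        sense = _random_seq(rng, mrna_length)
        start = emit(sense)
        name = f"GENE{i}"
        loci.append(
            NcRNALocus(
                locus_id=name,
                name=name,
                interval=GenomicInterval(chrom, start, start + mrna_length, "+"),
                rna_class="mRNA",
                sequence=sense,
            )
        )
        relatedness[name] = name

    for i in range(1, overlap_pairs + 1):
        emit_spacer()
        segment = _random_seq(rng, 2 * mrna_length - overlap_nt)
        start = emit(segment)
        for j, (name, offset) in enumerate(
            [(f"OVA{i}", 0), (f"OVB{i}", mrna_length - overlap_nt)]
        ):
            loci.append(
                NcRNALocus(
                    locus_id=name,
                    name=name,
                    interval=GenomicInterval(
                        chrom, start + offset, start + offset + mrna_length, "+"
                    ),
                    rna_class="mRNA",
                    sequence=segment[offset : offset + mrna_length],
                )
            )
            relatedness[name] = name
    emit_spacer()

    genome = {chrom: "".join(chunks)}
    clusters = build_clusters(loci, relatedness)
    spec_by_id = {s.family_id: s for s in specs}
    for cluster in clusters:
        spec = spec_by_id.get(cluster.cluster_id)
        if spec is not None and len(cluster.members) > 1:
            cluster.groups = partition_groups(
                kmer_similarity(cluster.members, k=k), threshold=1
            )
    return SyntheticGenome(
        genome=genome, loci=loci, relatedness=relatedness,
        clusters=clusters, seed=seed,
    )


# ---------------------------------------------------------------------------
# toy exact-match aligner

class KmerIndex:
    """Hash of every forward genomic k-mer to its (chrom, start) positions."""

    def __init__(self, genome: dict, k: int):
        self.k = k
        self._index: dict = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def placements(self, read_seq: str) -> list:
        """All exact placements of *read_seq*, both strands, sorted."""
        hits = [
            (chrom, start, "+")
            for chrom, start in self._index.get(read_seq, ())
        ]
        hits += [
            (chrom, start, "-")
            for chrom, start in self._index.get(reverse_complement(read_seq), ())
        ]
        return sorted(hits)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._index


@dataclass
class ToyAlignment:
    """Placements per read plus the unaligned-read counter."""

    alignments: list  # (read_id, seq, [(chrom, start, strand), ...])
    n_unaligned: int

    @property
    def n_aligned(self) -> int:
        return len(self.alignments)

    def write_sam(self, chrom_lengths: dict, path) -> None:
        samio.write_sam(self.alignments, chrom_lengths, path)


def toy_align(reads, genome, k: int | None = None) -> ToyAlignment:
    """Exact-match alignment of fixed-length reads against *genome*.

    Every placement on either strand is reported; reads absent from the
    genome are omitted from the output but counted.  *genome* may be a
    {chrom: seq} dict or a prebuilt :class:`KmerIndex`.
    """
    reads = list(reads)
    if k is None:
        k = len(reads[0][1]) if reads else DEFAULT_READ_LENGTH
    index = genome if isinstance(genome, KmerIndex) else KmerIndex(genome, k)
    aligned, n_unaligned = [], 0
    for read_id, seq in reads:
        if len(seq) != index.k:
            raise ValueError(
                f"read {read_id}: length {len(seq)} != index k {index.k}"
            )
        placements = index.placements(seq)
        if placements:
            aligned.append((read_id, seq, placements))
        else:
            n_unaligned += 1
    return ToyAlignment(alignments=aligned, n_unaligned=n_unaligned)


# ---------------------------------------------------------------------------
# read simulation

def member_rpkms_from_group(cluster: NcRNACluster, group_rpkms: dict) -> dict:
    """Split group-level true RPKMs into per-member RPKMs.

    Members of a group share its expression equally in expected-read terms:
    member i of group g (n_g members) gets r_i = R_g / n_g * L_eff / L_i, so
    that the group's expected unique-read count corresponds exactly to R_g at
    the cluster's effective length.
    """
    if cluster.groups is None:
        raise ValueError(f"cluster {cluster.cluster_id} has no groups")
    length_of = {m.locus_id: m.length for m in cluster.members}
    out = {}
    for g in cluster.groups:
        rpkm = group_rpkms[g.label]
        for mid in g.member_ids:
            out[mid] = rpkm / len(g.member_ids) * cluster.effective_length / length_of[mid]
    return out


@dataclass
class SimulatedReadSet:
    """Reads, alignments, and the truth table of one simulated sample."""

    reads: list            # (read_id, seq), shuffled
    alignment: ToyAlignment
    truth: pd.DataFrame
    sample: str
    aligned_total: int
    read_length: int
    chrom_lengths: dict

    def aligned_reads(self) -> list:
        """AlignedRead objects, as the quantification stage consumes them."""
        from .model import AlignedRead

        return [
            AlignedRead(
                read_id=read_id,
                length=self.read_length,
                alignments=[
                    GenomicInterval(c, s, s + self.read_length, st)
                    for c, s, st in placements
                ],
                sample=self.sample,
            )
            for read_id, _, placements in self.alignment.alignments
        ]

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / "reads.fastq",
            "sam": outdir / "alignments.sam",
            "truth": outdir / "truth.tsv",
        }
        samio.write_fastq(self.reads, paths["fastq"])
        self.alignment.write_sam(self.chrom_lengths, paths["sam"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_reads(
    syn: SyntheticGenome,
    expression: dict,
    n_aligned_total: int = 100_000,
    read_length: int = DEFAULT_READ_LENGTH,
    antisense_fraction: float = 0.0,
    unalignable_fraction: float = 0.15,
    sample: str = "sim",
    seed: int = 0,
) -> SimulatedReadSet:
    """Draw stranded reads at the given true per-locus RPKMs.

    Per-locus read counts are Poisson with mean
    ``rpkm * (length/1000) * (n_aligned_total/1e6)``; start positions are
    uniform within the locus; reads are emitted on the locus strand except
    for the antisense fraction.  Background reads from unannotated sequence
    top the alignable pool up to exactly *n_aligned_total*, so the RPKM
    denominator of the simulated sample is the requested total.  A further
    ``unalignable_fraction`` of all reads is random sequence absent from the
    genome (they align nowhere, mimicking the unalignable part of a run).
    Loci missing from *expression* get zero reads.
    """
    if not 0 <= antisense_fraction <= 1 or not 0 <= unalignable_fraction < 1:
        raise ValueError("fractions must lie in [0, 1) ")
    rng = np.random.default_rng(seed)
    k = read_length
    per_million = n_aligned_total / 1e6
    loci_by_id = {l.locus_id: l for l in syn.loci}
    unknown = sorted(set(expression) - set(loci_by_id))
    if unknown:
        raise ValueError(f"expression names unknown loci: {unknown}")

    raw_reads: list = []  # sequences only; ids assigned after shuffling
    truth_rows: list = []
    realized_of: dict = {}
    for locus_id, locus in loci_by_id.items():
        rpkm = float(expression.get(locus_id, 0.0))
        expected = rpkm * (locus.length / 1000.0) * per_million
        n_positions = locus.length - k + 1
        if n_positions < 1:
            raise ValueError(f"locus {locus_id} shorter than the read length")
        if expected > 100.0 * n_positions:
            warnings.warn(
                f"locus {locus_id}: expected count {expected:.0f} far exceeds "
                f"its {n_positions} distinct read positions", stacklevel=2,
            )
        realized = int(rng.poisson(expected)) if expected > 0 else 0
        realized_of[locus_id] = realized
        starts = rng.integers(0, n_positions, size=realized)
        flips = rng.random(realized) < antisense_fraction
        for start, flip in zip(starts, flips):
            seq = locus.sequence[start : start + k]
            raw_reads.append(reverse_complement(seq) if flip else seq)
        truth_rows.append(
            {
                "feature_id": locus_id,
                "scope": "mRNA" if locus.rna_class == "mRNA" else "member",
                "sample": sample,
                "true_rpkm": rpkm,
                "expected_count": expected,
                "realized_count": realized,
                "effective_length": float(locus.length),
            }
        )

    n_feature = len(raw_reads)
    n_background = n_aligned_total - n_feature
    if n_background < 0:
        warnings.warn(
            f"realized feature reads ({n_feature}) exceed n_aligned_total "
            f"({n_aligned_total}); no background reads added", stacklevel=2,
        )
        n_background = 0
    index = KmerIndex(syn.genome, k)
    raw_reads.extend(_background_reads(rng, syn, k, n_background))
    n_alignable = len(raw_reads)

    n_unalignable = round(n_alignable * unalignable_fraction / (1.0 - unalignable_fraction))
    for _ in range(n_unalignable):
        while True:
            seq = _random_seq(rng, k)
            if seq not in index and reverse_complement(seq) not in index:
                break
        raw_reads.append(seq)

    order = rng.permutation(len(raw_reads))
    reads = [
        (f"r{rank:07d}", raw_reads[i]) for rank, i in enumerate(order)
    ]
    alignment = toy_align(reads, index)

    # aggregate truth for clusters and groups
    for cluster in syn.clusters:
        if len(cluster.members) < 2 and cluster.groups is None:
            continue
        norm = (cluster.effective_length / 1000.0) * per_million
        scopes = [("cluster", cluster.cluster_id, cluster.member_ids)]
        if cluster.groups is not None:
            scopes += [
                ("group", f"{cluster.cluster_id}/{g.label}", list(g.member_ids))
                for g in cluster.groups
            ]
        for scope, fid, member_ids in scopes:
            expected = sum(
                float(expression.get(m, 0.0))
                * (loci_by_id[m].length / 1000.0) * per_million
                for m in member_ids
            )
            truth_rows.append(
                {
                    "feature_id": fid,
                    "scope": scope,
                    "sample": sample,
                    "true_rpkm": expected / norm,
                    "expected_count": expected,
                    "realized_count": sum(realized_of[m] for m in member_ids),
                    "effective_length": cluster.effective_length,
                }
            )

    return SimulatedReadSet(
        reads=reads,
        alignment=alignment,
        truth=pd.DataFrame(truth_rows),
        sample=sample,
        aligned_total=alignment.n_aligned,
        read_length=k,
        chrom_lengths=syn.chrom_lengths,
    )


def _background_reads(rng, syn: SyntheticGenome, k: int, n: int) -> list:
    """Reads from unannotated genome positions (never overlapping a locus)."""
    if n <= 0:
        return []
    pools: list = []
    for chrom, seq in syn.genome.items():
        mask = np.ones(len(seq) - k + 1, dtype=bool)
        for locus in syn.loci:
            if locus.interval.chrom != chrom:
                continue
            lo = max(0, locus.interval.start - k + 1)
            mask[lo : locus.interval.end] = False
        starts = np.flatnonzero(mask)
        if starts.size:
            pools.append((chrom, starts))
    if not pools:
        raise ValueError("no unannotated positions available for background reads")
    chrom_choice = rng.integers(0, len(pools), size=n)
    flips = rng.random(n) < 0.5
    out = []
    for ci, flip in zip(chrom_choice, flips):
        chrom, starts = pools[ci]
        start = int(starts[rng.integers(0, starts.size)])
        seq = syn.genome[chrom][start : start + k]
        out.append(reverse_complement(seq) if flip else seq)
    return out
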