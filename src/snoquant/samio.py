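"""SAM and FASTQ I/O for multi-mapped 28-nt reads.

SAM is consumed through pysam; every line of a multi-mapped read shares its
read_id and the lines are folded into one :class:`AlignedRead` carrying the
full placement set.  The writer emits plain text SAM (primary line first,
remaining placements flagged secondary) so toy-aligner fixtures stay
human-readable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pysam

from .model import AlignedRead, GenomicInterval, reverse_complement


def read_sam(path, sample: str = "") -> list:
    """Fold SAM lines into AlignedReads (one per read_id, all placements).

    Unmapped records are skipped; duplicates of the same placement are
    deduplicated by the AlignedRead constructor.
    """
    placements: dict = {}
    lengths: dict = {}
    order: list = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            iv = GenomicInterval(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
            )
            if rec.query_name not in placements:
                placements[rec.query_name] = []
                lengths[rec.query_name] = rec.reference_end - rec.reference_start
                order.append(rec.query_name)
            placements[rec.query_name].append(iv)
    return [
        AlignedRead(
            read_id=rid,
            length=lengths[rid],
            alignments=placements[rid],
            sample=sample,
        )
        for rid in order
    ]


def aligned_read_count(path) -> int:
    """Number of distinct aligned reads (the RPKM denominator)."""
    return len(read_sam(path))


def write_sam(alignments, reference_lengths: Mapping[str, int], path) -> None:
    """Write exact-match placements as text SAM.

    *alignments* is an iterable of ``(read_id, sequence, placements)`` where
    each placement is ``(chrom, start0, strand)``.  The first placement is
    primary; the rest carry the secondary flag.  Minus-strand lines store the
    reverse complement, as SAM requires.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        fh.write("@PG\tID:snoquant-toy-align\tPN:snoquant\n")
        for read_id, seq, placements in alignments:
            cigar = f"{len(seq)}M"
            qual = "I" * len(seq)
            for i, (chrom, start0, strand) in enumerate(placements):
                flag = (16 if strand == "-" else 0) | (256 if i > 0 else 0)
                out_seq = reverse_complement(seq) if strand == "-" else seq
                fh.write(
                    f"{read_id}\t{flag}\t{chrom}\t{start0 + 1}\t0\t{cigar}"
                    f"\t*\t0\t0\t{out_seq}\t{qual}\n"
                )


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list:
    """Read FASTQ into (read_id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
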