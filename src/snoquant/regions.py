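"""Strand-specific coverage and RPM over arbitrary genomic spans.

Used for novel-transcription discovery: a broad span can transcribe
continuously without any annotated gene, and strand-separated reads-per-
million (RPM) over the span, compared across tissues, reveals it.  Counting
is consistent with the quantification module: a unique read contributes once
per strand when any of its placements overlaps the span by >= 1 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .model import AlignedRead, GenomicInterval, NcRNALocus


@dataclass
class RegionProfile:
    """Per-strand unique-read counts, RPM, and binned coverage of one span.

    Bins tile the region exactly (the last bin may be short); a read's bin is
    the bin of its 5' end, clipped into the region for edge-straddling reads,
    so per-strand bin counts sum to the strand count.
    """

    region: GenomicInterval
    sample: str
    aligned_total: int
    plus_count: int
    minus_count: int
    plus_rpm: float
    minus_rpm: float
    bin_width: int
    bin_starts: np.ndarray
    plus_bins: np.ndarray
    minus_bins: np.ndarray

    def summed_strand_counts(self):
        """(plus, minus) totals over all bins — the 'summed expression' view."""
        return int(self.plus_bins.sum()), int(self.minus_bins.sum())


def _bin_edges(region: GenomicInterval, bin_width: int) -> np.ndarray:
    starts = np.arange(region.start, region.end, bin_width)
    return starts


def region_rpm(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    aligned_total: int,
    bin_width: int = 1000,
    sample: str = "",
    chrom_lengths: Mapping[str, int] | None = None,
) -> RegionProfile:
    """Strand-separated unique-read count, RPM, and bin coverage of *region*.

    A read contributes once to a strand when >= 1 of its placements on that
    strand overlaps the region by >= 1 nt; within-region multi-mapping does
    not multiply the count.  RPM = count / (aligned_total / 1e6).
    """
    if aligned_total <= 0:
        raise ValueError("aligned_total must be > 0")
    if chrom_lengths is not None:
        if region.chrom not in chrom_lengths:
            raise ValueError(f"region chromosome {region.chrom!r} not in genome")
        if region.end > chrom_lengths[region.chrom]:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} extends "
                f"beyond chromosome length {chrom_lengths[region.chrom]}"
            )
    bin_starts = _bin_edges(region, bin_width)
    n_bins = len(bin_starts)
    plus_bins = np.zeros(n_bins, dtype=np.int64)
    minus_bins = np.zeros(n_bins, dtype=np.int64)
    plus_count = minus_count = 0

    for read in reads:
        for strand, bins in (("+", plus_bins), ("-", minus_bins)):
            hit = next(
                (
                    a
                    for a in read.alignments
                    if a.strand == strand and a.overlaps(region)
                ),
                None,
            )
            if hit is None:
                continue
            if strand == "+":
                plus_count += 1
            else:
                minus_count += 1
            five = min(max(hit.five_prime, region.start), region.end - 1)
            bins[(five - region.start) // bin_width] += 1

    per_million = aligned_total / 1e6
    return RegionProfile(
        region=region,
        sample=sample,
        aligned_total=aligned_total,
        plus_count=plus_count,
        minus_count=minus_count,
        plus_rpm=plus_count / per_million,
        minus_rpm=minus_count / per_million,
        bin_width=bin_width,
        bin_starts=bin_starts,
        plus_bins=plus_bins,
        minus_bins=minus_bins,
    )


@dataclass
class NovelRegion:
    """A merged above-threshold window run with per-sample RPM."""

    region: GenomicInterval
    rpm_by_sample: dict
    novel: bool  # True when no same-strand annotated locus overlaps


def scan_novel_regions(
    reads: Iterable[AlignedRead],
    annotation: Iterable[NcRNALocus],
    aligned_totals: Mapping[str, int],
    window: int = 1000,
    min_rpm: float = 50.0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list:
    """Tile the genome in *window*-nt strand-specific windows, keep those with
    RPM >= min_rpm in any sample, merge adjacent survivors, and flag each
    merged region as novel when it overlaps no annotated locus on its strand.

    Window hits use each read's first placement (its primary alignment);
    final per-sample RPM of every merged region is recomputed with the exact
    unique-read overlap rule of :func:`region_rpm`.  The span boundaries are
    window-resolution: this is a generalized screen, not a base-precise
    segmentation.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    reads = list(reads)
    by_sample: dict = {}
    for read in reads:
        by_sample.setdefault(read.sample, []).append(read)
    for s in by_sample:
        if s not in aligned_totals:
            raise ValueError(f"no aligned_total supplied for sample {s!r}")

    # window counts keyed by (chrom, strand, window index), from primary 5' ends
    extents: dict = {}
    win_counts: dict = {s: {} for s in by_sample}
    for sample_name, sample_reads in by_sample.items():
        for read in sample_reads:
            aln = read.alignments[0]
            key = (aln.chrom, aln.strand, aln.five_prime // window)
            win_counts[sample_name][key] = win_counts[sample_name].get(key, 0) + 1
            extents[aln.chrom] = max(extents.get(aln.chrom, 0), aln.end)
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            extents[chrom] = max(extents.get(chrom, 0), length)

    passing: set = set()
    for sample_name, counts in win_counts.items():
        per_million = aligned_totals[sample_name] / 1e6
        for key, count in counts.items():
            if count / per_million >= min_rpm:
                passing.add(key)

    # merge adjacent passing windows per (chrom, strand)
    runs: list = []
    for chrom, strand in sorted({(c, s) for c, s, _ in passing}):
        idxs = sorted(w for c, s, w in passing if (c, s) == (chrom, strand))
        run_start = prev = idxs[0]
        for w in idxs[1:]:
            if w == prev + 1:
                prev = w
                continue
            runs.append((chrom, strand, run_start, prev))
            run_start = prev = w
        runs.append((chrom, strand, run_start, prev))

    annotation = list(annotation)
    results = []
    for chrom, strand, w0, w1 in runs:
        end = (w1 + 1) * window
        if chrom in extents:
            end = min(end, extents[chrom])
        region = GenomicInterval(chrom, w0 * window, end, strand)
        rpm_by_sample = {}
        for sample_name, sample_reads in by_sample.items():
            profile = region_rpm(
                sample_reads, region, aligned_totals[sample_name],
                bin_width=window, sample=sample_name,
            )
            rpm_by_sample[sample_name] = (
                profile.plus_rpm if strand == "+" else profile.minus_rpm
            )
        novel = not any(
            l.interval.overlaps(region, stranded=True) for l in annotation
        )
        results.append(NovelRegion(region=region, rpm_by_sample=rpm_by_sample, novel=novel))
    results.sort(key=lambda r: (r.region.chrom, r.region.start, r.region.strand))
    return results


# ---------------------------------------------------------------------------
# exports

def regions_to_bed(novel_regions, path) -> None:
    """BED6; score = max per-sample RPM x 10, rounded; name flags novelty."""
    with open(path, "w") as fh:
        for nr in novel_regions:
            iv = nr.region
            score = round(10 * max(nr.rpm_by_sample.values(), default=0.0))
            name = "novel" if nr.novel else "annotated"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def write_bedgraph(profile: RegionProfile, path, strand: str) -> None:
    """Per-strand binned coverage as bedGraph (0-based half-open)."""
    bins = profile.plus_bins if strand == "+" else profile.minus_bins
    with open(path, "w") as fh:
        for start, value in zip(profile.bin_starts, bins):
            end = min(start + profile.bin_width, profile.region.end)
            fh.write(f"{profile.region.chrom}\t{start}\t{end}\t{int(value)}\n")
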