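"""Annotation loading, class filtering, and ncRNA cluster assembly.

The annotation table is tab-separated with a header and columns
``locus_id, name, chrom, start, end, strand, rna_class, cluster`` where
``start``/``end`` are 1-based inclusive browser-style coordinates.  They are
converted to 0-based half-open on load and back on write.  Sequences are
extracted from the genome FASTA and reverse-complemented for minus-strand
loci, so every locus carries its sense (as-transcribed) sequence.

Clusters combine all genomic copies of "related" loci (e.g. a gene and its
``-related`` duplicates) into one feature while preserving every location.
The relatedness labeling is supplied explicitly as a two-column mapping, not
inferred from name suffixes.
"""

from __future__ import annotations

import statistics
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .model import (
    GenomicInterval,
    NcRNACluster,
    NcRNALocus,
    RNA_CLASSES,
    normalize_rna_class,
    reverse_complement,
)

#: Classes removed before ncRNA cluster quantification; tRNA/rRNA
#: quantification elsewhere passes its own ``excluded`` set to retain them.
DEFAULT_EXCLUDED_CLASSES = frozenset({"pseudogene", "miRNA", "tRNA", "rRNA"})

ANNOTATION_COLUMNS = [
    "locus_id",
    "name",
    "chrom",
    "start",
    "end",
    "strand",
    "rna_class",
    "cluster",
]


def read_genome(path) -> dict:
    """Load a FASTA into a {chrom: uppercase sequence} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def load_annotation(path, genome) -> list:
    """Load loci from an annotation TSV, extracting sequences from *genome*.

    Parameters
    ----------
    path : str or Path
        Annotation table (1-based inclusive coordinates, see module docs).
    genome : str, Path or dict
        FASTA path or an already-loaded {chrom: sequence} dict.

    Returns
    -------
    list of NcRNALocus in file order.  Minus-strand loci carry the reverse
    complement of the plus-strand genomic slice.
    """
    if not isinstance(genome, Mapping):
        genome = read_genome(genome)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS[:7] if c not in table.columns]
    if missing:
        raise ValueError(f"annotation {path}: missing column(s) {missing}")

    loci = []
    for row in table.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(
                f"annotation row {row.locus_id!r}: chromosome {row.chrom!r} "
                "not present in the genome FASTA"
            )
        if row.strand not in ("+", "-"):
            raise ValueError(
                f"annotation row {row.locus_id!r}: malformed strand {row.strand!r}"
            )
        start0 = int(row.start) - 1  # 1-based inclusive -> 0-based half-open
        end0 = int(row.end)
        chrom_seq = genome[row.chrom]
        if end0 > len(chrom_seq):
            raise ValueError(
                f"annotation row {row.locus_id!r}: end {row.end} beyond "
                f"{row.chrom} length {len(chrom_seq)}"
            )
        seq = chrom_seq[start0:end0]
        if row.strand == "-":
            seq = reverse_complement(seq)
        loci.append(
            NcRNALocus(
                locus_id=row.locus_id,
                name=row.name,
                interval=GenomicInterval(row.chrom, start0, end0, row.strand),
                rna_class=normalize_rna_class(row.rna_class),
                sequence=seq,
            )
        )
    return loci


def write_annotation(loci: Iterable[NcRNALocus], path, relatedness=None) -> None:
    """Write loci back to the annotation TSV format (1-based inclusive)."""
    relatedness = relatedness or {}
    rows = [
        {
            "locus_id": l.locus_id,
            "name": l.name,
            "chrom": l.interval.chrom,
            "start": l.interval.start + 1,
            "end": l.interval.end,
            "strand": l.interval.strand,
            "rna_class": l.rna_class,
            "cluster": relatedness.get(l.name, l.name),
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def filter_classes(loci, excluded=DEFAULT_EXCLUDED_CLASSES) -> list:
    """Drop loci whose class is in *excluded*; order preserved.

    Unknown class names in *excluded* raise ``ValueError`` so that a typo
    cannot silently disable part of the filter.
    """
    excluded_norm = {normalize_rna_class(c) for c in excluded}
    return [l for l in loci if l.rna_class not in excluded_norm]


def load_relatedness(path) -> dict:
    """Read a two-column TSV (name, cluster_name) into a mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"relatedness file {path}: expected two columns")
    name_col, cluster_col = table.columns[:2]
    return dict(zip(table[name_col], table[cluster_col]))


def build_clusters(loci, relatedness=None) -> list:
    """Group loci into named clusters of all their genomic locations.

    *relatedness* maps every locus **name** to a cluster name; ``None`` uses
    the identity mapping (one cluster per distinct name, so singleton genes
    stay singleton clusters while duplicated copies sharing a name merge).
    The RPKM ``effective_length`` of each cluster is the median member
    length — one copy's length, not the sum over all copies.
    """
    loci = list(loci)
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus_id(s) in annotation: {dupes}")
    if relatedness is None:
        relatedness = {l.name: l.name for l in loci}
    unmapped = sorted({l.name for l in loci if l.name not in relatedness})
    if unmapped:
        raise ValueError(
            f"locus name(s) missing from the relatedness mapping: {unmapped}"
        )

    by_cluster: dict = {}
    for locus in loci:  # insertion order fixes cluster order
        by_cluster.setdefault(relatedness[locus.name], []).append(locus)

    clusters = []
    for cluster_id, members in by_cluster.items():
        members = sorted(members, key=lambda l: (l.interval.chrom, l.interval.start))
        clusters.append(
            NcRNACluster(
                cluster_id=cluster_id,
                members=members,
                effective_length=float(statistics.median(m.length for m in members)),
            )
        )
    return clusters


def clusters_to_bed(clusters, path) -> None:
    """Export cluster members as BED6 (0-based half-open) for browser checks."""
    with open(path, "w") as fh:
        for cluster in clusters:
            for m in cluster.members:
                iv = m.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{cluster.cluster_id}/{m.locus_id}\t0\t{iv.strand}\n"
                )
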