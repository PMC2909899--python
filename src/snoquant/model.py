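"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open internally. File readers and writers
document their own convention (BED is 0-based half-open, browser-style
annotation text is 1-based inclusive) and convert on the way in and out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")

#: Closed vocabulary of feature classes. ``CD_box`` / ``HACA_box`` carry the
#: methylation vs pseudouridylation snoRNA distinction.
RNA_CLASSES = (
    "CD_box",
    "HACA_box",
    "scaRNA",
    "scRNA",
    "misc",
    "mRNA",
    "tRNA",
    "rRNA",
    "miRNA",
    "pseudogene",
    "lincRNA",
)

_CLASS_BY_FOLDED = {c.casefold(): c for c in RNA_CLASSES}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna_class(name: str) -> str:
    """Map *name* onto the closed class vocabulary, case-insensitively.

    Raises ``ValueError`` for anything outside the vocabulary: a silent typo
    in a class name would corrupt the class filter downstream.
    """
    try:
        return _CLASS_BY_FOLDED[name.strip().casefold()]
    except KeyError:
        raise ValueError(
            f"unknown RNA class {name!r}; expected one of {', '.join(RNA_CLASSES)}"
        ) from None


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True when the two spans share >= 1 nt (optionally same strand)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    @property
    def five_prime(self) -> int:
        """0-based position of the 5' end (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class NcRNALocus:
    """One annotated genomic copy of a feature, with its sense sequence."""

    locus_id: str
    name: str
    interval: GenomicInterval
    rna_class: str
    sequence: str

    def __post_init__(self) -> None:
        self.rna_class = normalize_rna_class(self.rna_class)
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"locus {self.locus_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Group:
    """A labeled subset of cluster members with no shared k-mers outside it."""

    label: str
    member_ids: tuple

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"group {self.label} has no members")


@dataclass
class NcRNACluster:
    """All genomic copies of a duplicated/related ncRNA family, quantified as one.

    ``effective_length`` is the length used for RPKM normalization; by default
    the median member length (one copy's length, not the sum over copies).
    ``groups``, when set, partition the members into read-discriminable
    subsets.
    """

    cluster_id: str
    members: list
    effective_length: float
    groups: list | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        if self.effective_length <= 0:
            raise ValueError(
                f"cluster {self.cluster_id}: effective_length must be > 0"
            )
        ids = [m.locus_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"cluster {self.cluster_id}: duplicate locus_id(s) {dupes}"
            )
        if self.groups is not None:
            seen: set = set()
            for g in self.groups:
                overlap = seen & set(g.member_ids)
                if overlap:
                    raise ValueError(
                        f"cluster {self.cluster_id}: member(s) {sorted(overlap)} "
                        "in more than one group"
                    )
                seen |= set(g.member_ids)
            if seen != set(ids):
                raise ValueError(
                    f"cluster {self.cluster_id}: groups do not partition members"
                )

    @property
    def member_ids(self) -> list:
        return [m.locus_id for m in self.members]


@dataclass
class AlignedRead:
    """A sequenced read with every genomic placement the aligner reported."""

    read_id: str
    length: int
    alignments: list
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError(f"read {self.read_id} has no alignments")
        deduped: list = []
        seen: set = set()
        for a in self.alignments:
            if len(a) != self.length:
                raise ValueError(
                    f"read {self.read_id}: alignment span {len(a)} nt "
                    f"!= read length {self.length} nt"
                )
            key = (a.chrom, a.start, a.strand)
            if key not in seen:
                seen.add(key)
                deduped.append(a)
        self.alignments = deduped


@dataclass(frozen=True)
class ExpressionRecord:
    """One (feature, sample) expression measurement.

    ``rpkm`` is reads per 1000 nt of feature length per million aligned reads;
    ``rpkm_sigma`` is the Poisson counting uncertainty sqrt(count) pushed
    through the same normalization.
    """

    feature_id: str
    scope: str
    sample: str
    count: int
    rpkm: float
    rpkm_sigma: float
    effective_length: float
    aligned_total: int

    SCOPES = ("mRNA", "cluster", "group", "member", "region")

    def __post_init__(self) -> None:
        if self.scope not in self.SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.count < 0:
            raise ValueError("negative count")
        if self.count > self.aligned_total:
            raise ValueError(
                f"{self.feature_id}: count {self.count} exceeds aligned total "
                f"{self.aligned_total}"
            )

    @classmethod
    def from_count(
        cls,
        feature_id: str,
        scope: str,
        sample: str,
        count: int,
        effective_length: float,
        aligned_total: int,
    ) -> "ExpressionRecord":
        from .quantify import rpkm_normalize

        rpkm, sigma = rpkm_normalize(count, aligned_total, effective_length)
        return cls(
            feature_id=feature_id,
            scope=scope,
            sample=sample,
            count=count,
            rpkm=rpkm,
            rpkm_sigma=sigma,
            effective_length=effective_length,
            aligned_total=aligned_total,
        )
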