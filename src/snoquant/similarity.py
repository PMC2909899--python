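"""Shared-k-mer similarity among cluster members and group partitioning.

A read of length k placed without mismatches is ambiguous between two family
members exactly when the members share an identical k-mer.  Counting distinct
shared 28-mers between every pair of members therefore measures read-level
mappability directly: members sharing no 28-mer can never compete for a read.

Groups are the connected components of the "shares >= threshold k-mers" graph.
Three outcomes matter in practice:

* every component a singleton  -> individual members are discriminable;
* several multi-member components -> group-level counting is possible
  (reads map within a group but never across groups);
* one single component -> only whole-cluster counting is meaningful.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .model import Group, NcRNACluster, NcRNALocus, reverse_complement

DEFAULT_K = 28

MEMBER_DISCRIMINABLE = "member-discriminable"
GROUP_DISCRIMINABLE = "group-discriminable"
CLUSTER_LEVEL_ONLY = "cluster-level-only"


class SimilarityMatrix:
    """Member x member counts of distinct shared k-mers.

    Diagonal entry (i, i) is the number of distinct k-mers in member i
    (at most length - k + 1, with equality iff all its k-mers are distinct).
    """

    def __init__(self, member_ids, counts, k):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(member_ids):
            raise ValueError("member_ids length does not match matrix size")
        if (counts < 0).any():
            raise ValueError("negative k-mer counts")
        self.member_ids = list(member_ids)
        self.counts = counts
        self.k = int(k)

    @property
    def is_symmetric(self) -> bool:
        return bool((self.counts == self.counts.T).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.member_ids, columns=self.member_ids
        )

    def to_tsv(self, path) -> None:
        """Write as TSV with member ids as header row and column."""
        self.to_frame().to_csv(path, sep="\t", index_label=f"k={self.k}")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        k = int(str(frame.index.name).split("=")[1])
        return cls(list(frame.columns), frame.to_numpy(), k)


def kmer_set(sequence: str, k: int, both_strands: bool = False) -> set:
    """Distinct k-mers of *sequence* (optionally plus reverse complements)."""
    kmers = {sequence[i : i + k] for i in range(len(sequence) - k + 1)}
    if both_strands:
        kmers |= {reverse_complement(m) for m in kmers}
    return kmers


def kmer_similarity(
    members: Iterable[NcRNALocus],
    k: int = DEFAULT_K,
    both_strands: bool = False,
) -> SimilarityMatrix:
    """Count distinct k-mers shared by every pair of members.

    Members shorter than ``k`` cannot receive a length-k read at all; they are
    excluded from the matrix with a warning rather than reported as spuriously
    dissimilar.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept, sets = [], []
    for m in members:
        if m.length < k:
            warnings.warn(
                f"member {m.locus_id} ({m.length} nt) shorter than k={k}; "
                "excluded from similarity matrix",
                stacklevel=2,
            )
            continue
        kept.append(m.locus_id)
        sets.append(kmer_set(m.sequence, k, both_strands=both_strands))

    n = len(kept)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        counts[i, i] = len(sets[i])
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(sets[i] & sets[j])
    return SimilarityMatrix(kept, counts, k)


def _roman(n: int) -> str:
    numerals = (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    )
    out = []
    for value, symbol in numerals:
        while n >= value:
            out.append(symbol)
            n -= value
    return "".join(out)


def partition_groups(matrix: SimilarityMatrix, threshold: int = 1) -> list:
    """Partition members into groups no read can cross.

    Groups are the connected components of the graph with an edge (i, j),
    i != j, whenever ``counts[i, j] >= threshold``.  Labels are Roman numerals
    assigned in order of each component's first member.
    """
    if not matrix.is_symmetric:
        raise ValueError("similarity matrix is not symmetric")
    n = len(matrix.member_ids)

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.counts[i, j] >= threshold:
                parent[find(i)] = find(j)

    components: dict = {}
    for i in range(n):  # index order => first-appearance order
        components.setdefault(find(i), []).append(i)

    return [
        Group(
            label=_roman(rank + 1),
            member_ids=tuple(matrix.member_ids[i] for i in idxs),
        )
        for rank, idxs in enumerate(components.values())
    ]


def classify_discriminability(groups) -> str:
    """How finely reads can attribute expression within the cluster."""
    if all(len(g.member_ids) == 1 for g in groups):
        return MEMBER_DISCRIMINABLE
    if len(groups) == 1:
        return CLUSTER_LEVEL_ONLY
    return GROUP_DISCRIMINABLE


def discriminability_report(
    cluster: NcRNACluster, matrix: SimilarityMatrix, read_length: int
) -> dict:
    """Per-member count of k-mers found in no other member.

    A member with zero unique k-mers can never receive a member-exclusive
    read of that length.  ``read_length`` must equal the matrix k so the
    report speaks about the reads actually being counted.
    """
    if read_length != matrix.k:
        raise ValueError(
            f"read_length {read_length} != matrix k {matrix.k}; the report "
            "would not describe the reads being counted"
        )
    seqs = {m.locus_id: m.sequence for m in cluster.members}
    sets = {
        mid: kmer_set(seqs[mid], matrix.k)
        for mid in matrix.member_ids
    }
    report = {}
    for mid in matrix.member_ids:
        others: set = set()
        for other_id, other_set in sets.items():
            if other_id != mid:
                others |= other_set
        report[mid] = len(sets[mid] - others)
    return report


def write_groups_tsv(groups, path) -> None:
    """Two-column TSV (locus_id, group_label)."""
    rows = [
        {"locus_id": mid, "group_label": g.label}
        for g in groups
        for mid in g.member_ids
    ]
    pd.DataFrame(rows, columns=["locus_id", "group_label"]).to_csv(
        path, sep="\t", index=False
    )
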