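# Methods

## The quantification problem

PolyA-neutral amplification makes non-polyadenylated transcripts — snoRNAs,
scRNAs, snRNAs, lincRNAs — visible to short-read sequencing, but many of
these RNAs exist as families of near-identical genomic copies. A 28-nt read
from such a family typically aligns to several copies at once, so per-locus
counting either discards most of the signal (unique-mapping filters) or
double-counts it (naive per-alignment counting). `snoquant` takes the
cluster route: all copies of a family are one feature, reads are counted
once per feature, and shared-k-mer analysis determines the finest scope at
which reads can still be attributed unambiguously.

## Reads

Raw reads are truncated from the 3' end to one common length (default
28 nt), which removes sequenced amplification primer from longer reads and
makes counts comparable across runs of different raw lengths; reads shorter
than the target are dropped and counted. All downstream logic treats a read
as its read_id plus the *set* of genomic placements reported by the aligner
(multi-mapped SAM lines sharing a read_id are folded into one record).

## k-mer similarity and groups

For members of a cluster, entry (i, j) of the similarity matrix is the
number of *distinct* k-mers (default k = 28, matching the read length)
present in both member i and member j — set semantics, not occurrence
pairs, because the question is mappability: can a perfect-match read of
length k be ambiguous between the two members? Groups are the connected
components of the graph with an edge wherever the shared count reaches the
threshold (default 1). By construction a perfect-match read of length k can
never be ambiguous between two groups, which is what makes group-level
unique-read counting exact rather than heuristic. Three regimes fall out:
all-singleton components (members individually quantifiable), several
multi-member components (group-level quantification), one component
(cluster-level only). Members are already strand-resolved sense sequences,
so reverse-complement k-mers are excluded by default; a `both_strands` flag
exists for unstranded use. Members shorter than k are excluded with a
warning rather than reported as dissimilar. Group labels are Roman numerals
in order of first member appearance along the genome, so output is
deterministic.

## Counting

* **mRNA**: a read counts for a gene iff the set of genes overlapped by any
  of its placements has size exactly one and at least one placement overlaps
  that gene on the gene's strand. Reads inside overlapping gene pairs are
  excluded from both genes by the single-gene condition.
* **cluster**: a read counts once iff >= 1 placement overlaps >= 1 member on
  the correct strand. The default *lenient* mode ignores placements outside
  the cluster (the cluster merged all related locations precisely so those
  reads stay countable); *strict* mode drops any read with a non-member
  placement.
* **group**: among a read's member-overlapping, strand-correct placements,
  the set of groups touched decides the assignment — one group: that group;
  two or more: the ambiguous bin. The ambiguous bin is always reported, so
  the conservation identity `sum(group counts) + ambiguous == cluster count`
  is checkable from outputs alone (the pipeline runner enforces it and exits
  nonzero on violation). Member-level counting is group counting with every
  member its own group, i.e. member-exclusive reads only.
* **overlap predicate**: >= 1 nt intersection, not containment — with 28-nt
  reads and ~81-nt features, edge overlaps are common and real.
* **simple features**: tRNA-style quantification is full RPKM;
  lincRNA-style quantification is reads-per-million only (no length term),
  since for broad loosely-defined spans a per-kb density is less meaningful
  than the read total.

## Normalization and uncertainty

RPKM = count / (L/1000) / (N/1e6) with N the number of *distinct aligned
reads* in the sample (not alignments; no class excluded from the
denominator) and L the feature's effective length. For a cluster, L is the
**median member length** — one copy's length. The alternative (summing all
copies) would divide a cluster's shared expression by an ~n-fold larger
length and make cluster RPKMs incomparable with single-copy features;
median rather than mean keeps one aberrantly annotated copy from shifting
L. Counts are Poisson distributed under the model, so sigma(count) =
sqrt(count), and the RPKM uncertainty is sqrt(count) pushed through the
identical normalization. Every output row carries count, rpkm, rpkm_sigma,
effective_length and aligned_total so the algebra is auditable row by row.

Tissue-enrichment tallies classify a feature as expressed when its maximum
RPKM across samples exceeds a threshold (default 10) and assign it to its
argmax sample; ties are broken by fixed sample order **and flagged** rather
than silently resolved.

## Regions

`region_rpm` counts unique reads per strand over a span (once per strand,
however many within-span placements) and returns RPM plus per-bin counts;
bins tile the span exactly and a read falls in the bin of its 5' end, so
bin sums equal strand counts. `scan_novel_regions` tiles the genome with
fixed windows (default 1000 nt), keeps windows whose strand-specific RPM
reaches a threshold in any sample, merges adjacent survivors, recomputes
each merged span's per-sample RPM with the exact overlap rule, and flags
spans with no same-strand annotated overlap as novel. This scan is a
generalized screen with window-resolution boundaries, not a changepoint
segmentation; window hits use each read's primary placement for speed, the
final RPMs do not.

## Synthetic data

The generator emulates the data regime the pipeline targets, with defaults
fixed at the study conditions:

* families of 81-nt members (a typical snoRNA length) in groups — e.g. the
  29-member, 9/15/5 demo family; within-group divergence 2 substitutions
  per member (members still share most 28-mers), between-group divergence
  member_length/3 substitutions from a common family ancestor;
* group structure is *certified, not assumed*: candidate families are
  redrawn (bounded retries) until the similarity module itself partitions
  them into exactly the requested group sizes with zero cross-group 28-mer
  sharing;
* reads: per-locus counts ~ Poisson(true_rpkm x L/1000 x N/1e6), start
  positions uniform within the locus (no 5'-bias model — the simplest model
  that keeps the Poisson count math exact), emitted on the locus strand
  except an antisense fraction (default 0, matching a strand-preserving
  protocol); background reads from unannotated sequence top the alignable
  pool up to exactly N, so the RPKM denominator is the nominal total; a
  further 15% of all reads is random sequence absent from the genome
  (unalignable, matching the observed ~79–90% alignable range);
* the toy aligner is exact-match only and reports *every* placement on both
  strands via a k-mer hash of the genome. At 28 nt this is the clean regime
  in which "reads never cross groups" is provable and group-count
  conservation is exactly testable; mismatch tolerance is deliberately out
  of scope.

Everything is deterministic given the seed, to the byte, across FASTA /
FASTQ / SAM / truth-table outputs.

What the simulation does **not** model: sequencing errors and quality
scores, positional/GC bias, rRNA depletion artifacts, amplification
chemistry, and mismatch-tolerant alignment. Passing tests therefore
demonstrate the counting, grouping and normalization logic — not robustness
to alignment noise in real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the parameter-recovery
simulation at 100,000 aligned reads against the three-group family at true
group RPKMs 14439 / 635 / 242; at that depth the expected group counts are
~117 / 5 / 2, so the small groups are recovered with wide (but correctly
reported) Poisson error bars — recovery is asserted within 3 sigma. Oracle
cross-checks use 20 random 200-nt sequences (k-mer set intersection), 10^4
reads x 100 features (naive double-loop counting), and a 10^5-nt genome
(full-scan alignment). The full demo pipeline runs in a few seconds on one
CPU. Degenerate inputs fail loudly: zero aligned totals or lengths, absent
chromosomes, malformed strands, asymmetric matrices, unmapped locus names
and unknown RNA classes are all fatal with the offending record named.

## Known limitations

* Group partitioning at threshold 1 is one defensible operationalization of
  "groups no read can cross"; a curated partition of a real family may
  differ at higher thresholds or under mismatch-tolerant alignment.
* Lenient unique-mode can count a read whose best placement is genuinely
  elsewhere in the genome; strict mode exists for that concern.
* The effective-length convention (median member length) is a modeling
  choice; comparisons against pipelines that normalize by summed copy
  length require rescaling.
* The novel-region scan's boundaries are window-quantized and its
  window-hit pass uses primary placements only.
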