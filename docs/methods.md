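# Methods

## Problem and model

Pseudogenes — genomic copies of genes that have lost coding ability — can be
transcribed, and when a long non-coding RNA (lncRNA) gene overlaps a
pseudogene the two loci can regulate each other (and the pseudogene's
parental gene) through sense–antisense hybridization, short-RNA biogenesis,
and promoter-level effects. `pseudolap` finds and scores such overlaps from
standard annotation files, classifies the transcription evidence at each
overlap, and builds positionally non-redundant pseudogene catalogs.

All coordinates are 1-based inclusive (GTF convention); BED inputs are
converted on read. A gene model is a non-empty set of exons on one
chromosome and strand, grouped by `gene_id`; its *span* runs from the
minimum exon start to the maximum exon end. A gene whose exon rows fall on
several chromosomes or strands is split into per-chrom/strand models with
suffixed IDs, because the overlap scores presume a single span.

## Overlap scores

For genes 1 and 2 with spans S1, S2 and shared span length `ov`:

    P1 = ov / |S1|,  P2 = ov / |S2|,  SS = P1 · P2

SS is 1 exactly when the spans are identical and 0 when they are disjoint
(a different-chromosome pair scores 0 rather than erroring). For exons, every
exon pair (i, j) with at least one shared base contributes

    E_ij = (shared / |exon_i|) · (shared / |exon_j|)

and the exon–exon score divides the summed pair scores by the total number
of unique exon loci

    TE = (#exons of gene 1) + (#exons of gene 2 overlapping no gene-1 exon),
    EE = Σ E_ij / TE,

so two genes with identical exon structures score EE = 1. EE is anchored on
gene 1; the pipeline always passes the pseudogene first. "Overlapping no
gene-1 exon" is read as ≥ 1 bp overlap (the same overlap semantics used
everywhere else); an exact-coordinate-identity reading is available via
`te_exclusion="identity"`, but under it TE would almost always equal the sum
of both exon counts and EE would deflate for near-identical genes. Overlap
arithmetic ignores strand entirely; relative orientation (sense when strands
match, antisense otherwise) is reported as a separate label. All pairs with
positive overlap contribute an E term, including several pairs sharing one
exon.

## Chained intersections and directionality

The pipeline intersects a pseudogene set with a lncRNA set in *exon mode*:
a pseudogene survives only if at least one of its exons shares a base with a
lncRNA exon, and only the matched exons are retained in the output model
(*span mode*, which requires only span overlap, is available for exploratory
use). Each surviving locus is then annotated with full-length cDNA and EST
partners, intersected in exon mode against the retained exons; loci with no
partner at a tier are absent from that tier. The retained-exon set is not
pruned further by the evidence step, so downstream exon-level overlays (for
example piRNA support) are measured on exons supported by both the lncRNA
annotation and the transcriptome evidence.

EST records carry a `read_end` attribute (configurable key): 3′ reads are
conventionally reported on the strand opposite the transcript, so their
stated orientation is reverted before use; 5′ and unknown reads pass through.
The flip touches only the strand and is involutive.

Per locus and evidence tier, the directionality call is *sense-only*,
*antisense-only*, or *bidirectional* (≥ 1 sense and ≥ 1 antisense partner,
orientations always relative to the pseudogene). The combined cDNA-and-EST
tier requires the same condition in both single tiers independently; loci
whose two tiers disagree get no combined call, so the three combined
categories need not partition the both-tier locus set. The *high-confidence*
set is the loci bidirectional in both tiers.

The summary tables report, per run and tier, the locus total and its
partition into all-sense / all-antisense / mixed-orientation ("complex")
loci — for the base row by lncRNA partner orientation, for evidence rows by
the tier's evidence partners (for the combined row, the union of both
tiers' partners, keeping the partition exact). Gene-ID counting is used
throughout the tier tables; positional locus collapse is a separate stage.

## Output dialect

The annotated output devotes a single exon-typed GTF line to each surviving
pseudogene gene ID, spanning the gene and carrying the original attributes
plus: `retained_exons` (`start-end` comma-joined), `intersects` with one
`(partnerID:SS:orientation:EE)` group per lncRNA partner in input order, and
`cdna_support` / `est_support` with the same format for evidence partners.
Scores are computed at full floating precision and rounded to 4 decimals
only at serialization. The file parses under the ordinary GTF reader;
`read_annotated_gtf` round-trips the full locus structure. Outputs are
sorted by (chrom, span start, gene ID) for reproducible diffs.

## Positional redundancy elimination

Records are clustered per chromosome by single-linkage span overlap
(transitive: spans A–B and B–C overlapping place A, B, C in one cluster)
and each cluster is collapsed to the member with the lowest span start
(input order, then gene ID, break ties) — keeping that member's whole
record rather than constructing a union interval. The result has zero
pairwise span overlaps and the operation is idempotent. A sequential
keep-first-entry scan over a start-sorted file yields the same
representatives; single-linkage makes the result independent of input
order. Clustering is strand-agnostic by default, since one locus annotated
on opposite strands by two databases is still one locus; a `stranded`
switch is provided. Merging catalogs concatenates them, collapses, and
reports per-source non-redundant counts plus Venn cells keyed by the set of
sources contributing members to each merged cluster.

## Overlay statistics

A locus is piRNA-supported when any retained exon shares ≥ 1 base with a
piRNA interval; a piRNA inside the span but wholly intronic does not count.
The mean piRNA-IDs-per-locus aggregate averages over supported loci only.
SNP proximity is measured against the gene's full span (not the retained
exons): a SNP hits when it lies inside the span or within the window
(default 10 000 bp) of either end, inclusive at both boundaries, so a SNP at
exactly `span.end + 10000` is a hit and one base further is not. With
window 0 exactly the inside-span SNPs are returned.

Support proportions of two locus sets are compared with the pooled
two-proportion z-test, one-tailed, without continuity correction:

    z = (x1/n1 − x2/n2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2)),  p̂ = (x1+x2)/(n1+n2)

On the reference counts 367/1167 vs 109/313 this gives z = −1.1355. The exact
lower-tail p of that statistic is 0.12808; the historically reported
p = 0.12714 is the tail of z rounded to two decimals (a z-table lookup at the
statistic's printed precision), so the test exposes `z_decimals` to
reproduce that convention while returning the exact tail by default. When
the pooled proportion is exactly 0 or 1 the statistic is undefined and
reported as NaN. Support percentages are rounded half-up to 2 decimals.

## Synthetic fixtures

The fixture generator emulates the input ecosystem — pseudogene GTF, lncRNA
GTF, cDNA and EST GTFs, piRNA BED, SNP TSV — on a toy genome of three 1 Mb
chromosomes. Each planted locus occupies its own 40 kb slot so loci cannot
interact, and follows an explicit directive: lncRNA partner orientation
(sense / antisense / both / none / intronic-only), cDNA and EST partner
orientations, exon count (1–5, exon lengths 120–400 bp, introns
250–700 bp), piRNA placement (on the shared exon, intronic, or absent), and
SNP placement (inside the span, within the 10 kb window, outside it, or
absent). Directives requesting evidence partners without an exon-overlapping
lncRNA anchor are rejected as contradictory. 3′-tagged ESTs are emitted on
the biologically wrong strand (with `read_end "3prime"`), which makes the
orientation-normalization step causally observable in the directionality
calls. The same seed and spec produce byte-identical files.

The truth table records, per locus, the expected surviving status, retained
exons, partner IDs with orientations and SS/EE scores, per-tier calls,
high-confidence flag, piRNA support, and SNP hits. Truth scores are computed
by per-base position-set arithmetic, independent of the closed-form interval
arithmetic in the scoring module, so the end-to-end truth comparison is a
genuine dual-route check. A separate catalog generator plants three
overlapping pseudogene "databases" with controlled accession synonymy
(random membership, jittered spans) and known Venn structure for merge
tests.

What the fixtures deliberately do not emulate: genome-scale annotation
density, real repeat content, overlapping neighbouring loci, EST library
artifacts (unspliced/singleton or artificial-promoter reads), or the sizes
of real public catalogs. Passing the planted-truth tests therefore certifies
the interval machinery and classification logic, not catalog-scale counts on
real data — reproducing those requires the original database snapshots,
which the package does not download.

## Problem sizes and numerical choices

The verification battery runs at desk scale by design: 20 random fixtures of
12 loci for end-to-end truth checks, 1000 random gene pairs against the
per-base oracle, 100 random catalog triples for collapse invariants, and
10 000 null replicates (n = 500 per side, true proportion 0.4) for z-test
calibration at α = 0.05, where the rejection rate is required to sit within
0.012 of α (five binomial standard deviations plus discreteness slack).
Scores compare to oracles at 1e-12 absolute tolerance; truth-table scores at
1e-9. Ties in representative selection and output ordering are broken
deterministically as described above. Degenerate inputs (empty sets,
different chromosomes, zero-width windows, pooled proportion 0 or 1) follow
the contracts stated in the docstrings rather than raising, except where an
input is unusable (zero sample size, malformed GTF lines, which are rejected
with the offending line number).

## Known limitations

- Overlap is purely positional; no sequence similarity, alignment, or
  parental-gene assignment is computed.
- Tier tables count gene IDs, not collapsed positional loci; combining the
  two accountings (as in a multi-block/single-block locus census) is left to
  the caller via the collapse stage.
- The EST read-end convention is taken from a GTF attribute; annotation
  sources that encode clone ends differently need a pre-mapping step.
- No liftover between assemblies and no download clients; inputs must share
  one assembly.
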