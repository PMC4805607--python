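"""Interval arithmetic and the two reciprocal overlap-scoring formulas.

The span-span score of a gene pair multiplies the fraction of span 1 covered
by span 2 by the fraction of span 2 covered by span 1, so it runs from 0 (no
shared base) to 1 (identical coordinates). The exon-exon score applies the
same product to every overlapping exon pair and divides the summed pair
scores by the total number of unique exon loci: all exons of gene 1 plus the
exons of gene 2 that overlap no gene-1 exon. Overlap computations ignore
strand; relative orientation is reported separately.
"""

from __future__ import annotations

from .models import GeneModel, GenomicInterval, Orientation, OverlapScore


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared base count of two closed intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def span_span_score(g1: GeneModel, g2: GeneModel) -> tuple[float, float, float]:
    """Reciprocal span coverage fractions (P1, P2) and their product SS.

    SS is 1 iff the spans are identical and 0 iff they are disjoint (including
    the different-chromosome case, which scores 0 by contract).
    """
    s1, s2 = g1.span, g2.span
    ov = overlap_length(s1, s2)
    p1 = ov / s1.length
    p2 = ov / s2.length
    return p1, p2, p1 * p2


def exon_exon_score(
    g1: GeneModel, g2: GeneModel, te_exclusion: str = "overlap"
) -> tuple[tuple[tuple[int, int, float], ...], int, float]:
    """Exon-pair scores, unique-exon total TE, and the exon-exon score EE.

    Every exon pair sharing at least one base contributes
    ``E = (covered fraction of exon 1) * (covered fraction of exon 2)``.
    ``TE`` counts all gene-1 exons plus the gene-2 exons that share no
    coordinates with any gene-1 exon; ``EE = sum(E) / TE``, so genes with
    identical exon structures score 1. EE is defined relative to gene 1 — the
    pipeline always passes the pseudogene first.

    ``te_exclusion`` picks the reading of "shares coordinates" for the TE
    exclusion: ``"overlap"`` (default) excludes gene-2 exons with >= 1 bp
    overlap; ``"identity"`` excludes only exact coordinate matches.
    """
    if te_exclusion not in ("overlap", "identity"):
        raise ValueError(f"unknown te_exclusion {te_exclusion!r}")
    pairs: list[tuple[int, int, float]] = []
    g2_shares: set[int] = set()
    for i, e1 in enumerate(g1.exons):
        for j, e2 in enumerate(g2.exons):
            ov = overlap_length(e1, e2)
            if ov <= 0:
                continue
            pairs.append((i, j, (ov / e1.length) * (ov / e2.length)))
            if te_exclusion == "overlap" or (e1.start, e1.end) == (e2.start, e2.end):
                g2_shares.add(j)
    te = len(g1.exons) + (len(g2.exons) - len(g2_shares))
    ee = sum(e for _, _, e in pairs) / te
    return tuple(pairs), te, ee


def score_pair(
    g1: GeneModel, g2: GeneModel, te_exclusion: str = "overlap"
) -> OverlapScore:
    """Full span + exon scoring of an (anchor, partner) gene pair."""
    p1, p2, ss = span_span_score(g1, g2)
    pairs, te, ee = exon_exon_score(g1, g2, te_exclusion=te_exclusion)
    return OverlapScore(P1=p1, P2=p2, SS=ss, exon_pair_scores=pairs, TE=te, EE=ee)


def relative_orientation(g1: GeneModel, g2: GeneModel) -> Orientation:
    """Sense when the two genes share a strand, antisense otherwise."""
    return Orientation.SENSE if g1.strand == g2.strand else Orientation.ANTISENSE
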