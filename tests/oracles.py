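"""Brute-force per-base reference implementations used only by the tests.

These enumerate integer genomic positions as Python sets, independently of
the closed-form interval arithmetic in the package, so they can serve as
oracles for the span-span and exon-exon scores.
"""

from __future__ import annotations

from pseudolap.models import GeneModel, GenomicInterval


def positions(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for p in range(iv.start, iv.end + 1)}


def brute_overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(positions(a) & positions(b))


def brute_span_span(g1: GeneModel, g2: GeneModel) -> tuple[float, float, float]:
    s1, s2 = positions(g1.span), positions(g2.span)
    ov = len(s1 & s2)
    p1, p2 = ov / len(s1), ov / len(s2)
    return p1, p2, p1 * p2


def brute_exon_exon(g1: GeneModel, g2: GeneModel) -> tuple[int, float]:
    """(TE, EE) by enumerating exon pairs over per-base position sets."""
    total = 0.0
    g2_sharing: set[int] = set()
    for e1 in g1.exons:
        b1 = positions(e1)
        for j, e2 in enumerate(g2.exons):
            b2 = positions(e2)
            ov = len(b1 & b2)
            if ov:
                total += (ov / len(b1)) * (ov / len(b2))
                g2_sharing.add(j)
    te = len(g1.exons) + len(g2.exons) - len(g2_sharing)
    return te, total / te


def brute_overlap_clusters(spans: list[tuple[str, int, int]]) -> list[set[int]]:
    """Single-linkage clusters over the pairwise span-overlap graph."""
    n = len(spans)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = spans[i]
            cj, sj, ej = spans[j]
            if ci == cj and si <= ej and sj <= ei:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    clusters = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        clusters.append(comp)
    return clusters
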