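"""Positional redundancy elimination and non-redundant catalog merging.

Multiple annotation records (accession synonyms, or the same locus annotated
by different databases) often occupy overlapping genomic spans. Records are
clustered by single-linkage span overlap on each chromosome — strand-agnostic
by default, since a locus annotated on opposite strands by two databases is
still one locus — and each cluster is collapsed to its lowest-start member,
leaving a set of mutually non-overlapping loci. Merging several catalogs
concatenates them, collapses, and reports per-source and Venn-cell counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .models import GeneModel, LocusCluster


@dataclass
class CatalogReport:
    """Counts from a multi-catalog merge.

    ``per_source`` holds each catalog's own non-redundant count;
    ``merged_count`` the size of the joint non-redundant set; ``venn`` maps a
    sorted tuple of source tags (a Venn cell) to the number of merged loci
    whose cluster drew members from exactly those sources. Venn cells sum to
    the merged count.
    """

    per_source: dict[str, int]
    merged_count: int
    venn: dict[tuple[str, ...], int]


def cluster_by_position(
    models: Sequence[GeneModel], stranded: bool = False
) -> list[LocusCluster]:
    """Single-linkage clusters of span-overlapping models per chromosome.

    Two models are linked when their spans share >= 1 bp (same strand also
    required when ``stranded``); linkage is transitive, so a chain of
    pairwise-overlapping spans forms one cluster. Deterministic given the
    input order; the representative is the member with the lowest span start,
    ties broken by input order then gene ID.
    """
    parent = list(range(len(models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[object, IntervalTree] = {}
    for idx, m in enumerate(models):
        span = m.span
        key = (span.chrom, span.strand) if stranded else span.chrom
        tree = trees.setdefault(key, IntervalTree())
        for iv in tree.overlap(span.start, span.end + 1):
            union(idx, iv.data)
        tree.addi(span.start, span.end + 1, idx)

    groups: dict[int, list[int]] = {}
    for idx in range(len(models)):
        groups.setdefault(find(idx), []).append(idx)

    clusters = []
    for member_idx in groups.values():
        members = [models[i] for i in member_idx]
        rep = min(
            zip(member_idx, members),
            key=lambda t: (t[1].span.start, t[0], t[1].gene_id),
        )[1]
        clusters.append(
            LocusCluster(
                members=members,
                representative=rep,
                provenance=frozenset(m.source for m in members),
            )
        )
    clusters.sort(
        key=lambda c: (c.representative.chrom, c.representative.span.start,
                       c.representative.gene_id)
    )
    return clusters


def collapse(clusters: Sequence[LocusCluster]) -> list[GeneModel]:
    """One representative per cluster; the output is positionally non-redundant.

    The whole original record (exons, attributes) of the chosen member is
    kept; no interval union is constructed. Idempotent:
    ``collapse(cluster(collapse(...)))`` returns the same set.
    """
    return [c.representative for c in clusters]


def collapse_models(
    models: Sequence[GeneModel], stranded: bool = False
) -> list[GeneModel]:
    """Cluster and collapse in one step."""
    return collapse(cluster_by_position(models, stranded=stranded))


def merge_catalogs(
    catalogs: Sequence[tuple[str, Sequence[GeneModel]]],
    stranded: bool = False,
) -> tuple[list[GeneModel], CatalogReport]:
    """Merge >= 2 catalogs into a positionally non-redundant superset.

    Each catalog is also collapsed alone for the per-source counts; each
    merged cluster's provenance (which sources contributed members)
    determines its Venn cell. The merged set is invariant to catalog order
    up to representative identity.
    """
    if len(catalogs) < 2:
        raise ValueError("merge_catalogs needs at least 2 catalogs")
    per_source = {
        tag: len(collapse_models(models, stranded=stranded))
        for tag, models in catalogs
    }
    pooled: list[GeneModel] = []
    for tag, models in catalogs:
        for m in models:
            if m.source != tag:
                m = GeneModel(
                    gene_id=m.gene_id,
                    transcript_ids=m.transcript_ids,
                    source=tag,
                    exons=list(m.exons),
                    attributes=dict(m.attributes),
                )
            pooled.append(m)
    clusters = cluster_by_position(pooled, stranded=stranded)
    merged = collapse(clusters)
    venn = Counter(tuple(sorted(c.provenance)) for c in clusters)
    report = CatalogReport(
        per_source=per_source,
        merged_count=len(merged),
        venn=dict(venn),
    )
    return merged, report
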