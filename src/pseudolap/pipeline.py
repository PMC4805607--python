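"""Chained pseudogene x lncRNA x transcription-evidence intersections.

The pipeline anchors on a pseudogene set, intersects it with a lncRNA set
(exon mode: at least one exon pair must share a base, and only the matched
pseudogene exons are retained), then annotates each surviving locus with
full-length cDNA and EST partners overlapping the retained exons. Partner
orientations are always measured relative to the pseudogene. Per-locus
directionality is classified at three evidence tiers (cDNA, EST, and both);
the high-confidence set is the loci bidirectional in both tiers
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import format_attributes, read_gtf
from .models import (
    Call,
    DirectionalityCall,
    GeneModel,
    GenomicInterval,
    IntersectAnnotation,
    Orientation,
    Tier,
)
from .scoring import overlap_length, relative_orientation, score_pair

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    """A focal pseudogene surviving the lncRNA intersect, plus its partners.

    ``model`` carries only the retained (lncRNA-matched) exons; ``original``
    is the pre-filter gene model. ``lncrna`` holds the lncRNA partner
    annotations and ``evidence`` the per-tier cDNA/EST partner annotations.
    """

    model: GeneModel
    original: GeneModel
    lncrna: list[IntersectAnnotation] = field(default_factory=list)
    evidence: dict[Tier, list[IntersectAnnotation]] = field(default_factory=dict)

    @property
    def locus_id(self) -> str:
        return self.model.gene_id


def _span_tree_by_chrom(models: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, m in enumerate(models):
        span = m.span
        trees.setdefault(span.chrom, IntervalTree()).addi(
            span.start, span.end + 1, idx
        )
    return trees


def intersect(
    focal: Sequence[GeneModel],
    partner: Sequence[GeneModel],
    mode: str = "exon",
    te_exclusion: str = "overlap",
) -> list[tuple[GeneModel, list[IntersectAnnotation]]]:
    """Mark focal genes overlapping any partner gene and score each pair.

    ``span`` mode keeps every focal gene whose span shares >= 1 bp with a
    partner span, with one annotation (SS, orientation relative to the focal
    gene, EE) per overlapping partner. ``exon`` mode additionally requires at
    least one exon pair with positive overlap, records only such partners,
    and retains in the returned model only the focal exons matched by some
    partner exon. Focal genes with no qualifying partner are dropped.
    """
    if mode not in ("span", "exon"):
        raise ValueError(f"unknown intersect mode {mode!r}")
    if not focal or not partner:
        logger.warning(
            "intersect: empty %s set; empty result",
            "focal" if not focal else "partner",
        )
        return []
    trees = _span_tree_by_chrom(partner)
    out: list[tuple[GeneModel, list[IntersectAnnotation]]] = []
    for g in focal:
        span = g.span
        tree = trees.get(span.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(span.start, span.end + 1))
        annotations: list[IntersectAnnotation] = []
        matched_exons: set[int] = set()
        for idx in hits:
            p = partner[idx]
            score = score_pair(g, p, te_exclusion=te_exclusion)
            if mode == "exon" and not score.exon_pair_scores:
                continue
            annotations.append(
                IntersectAnnotation(
                    partner_gene_id=p.gene_id,
                    SS=score.SS,
                    orientation=relative_orientation(g, p),
                    EE=score.EE,
                )
            )
            matched_exons.update(i for i, _, _ in score.exon_pair_scores)
        if not annotations:
            continue
        if mode == "exon":
            kept = [e for i, e in enumerate(g.exons) if i in matched_exons]
            out.append((g.with_exons(kept), annotations))
        else:
            out.append((g, annotations))
    out.sort(key=lambda t: (t[0].chrom, t[0].span.start, t[0].gene_id))
    return out


def anchor_loci(
    pseudogenes: Sequence[GeneModel],
    lncrnas: Sequence[GeneModel],
    te_exclusion: str = "overlap",
) -> list[Locus]:
    """Exon-mode pseudogene x lncRNA intersect packaged as Locus objects."""
    by_id = {g.gene_id: g for g in pseudogenes}
    result = intersect(pseudogenes, lncrnas, mode="exon", te_exclusion=te_exclusion)
    return [
        Locus(model=m, original=by_id[m.gene_id], lncrna=anns)
        for m, anns in result
    ]


def chain_evidence(
    anchored: Sequence[Locus],
    evidence: Sequence[GeneModel],
    tier: Tier | str,
    te_exclusion: str = "overlap",
) -> list[Locus]:
    """Annotate anchored loci with evidence partners overlapping retained exons.

    Evidence (cDNA or EST) genes are intersected in exon mode against the
    retained exons of each locus; orientation is relative to the pseudogene.
    Loci without any partner at the tier are excluded from the tier's output;
    the retained exon set itself is not pruned further.
    """
    tier = Tier(tier)
    models = [locus.model for locus in anchored]
    hits = dict(
        (m.gene_id, anns)
        for m, anns in intersect(
            models, evidence, mode="exon", te_exclusion=te_exclusion
        )
    )
    out: list[Locus] = []
    for locus in anchored:
        anns = hits.get(locus.locus_id)
        if not anns:
            continue
        locus.evidence[tier] = anns
        out.append(locus)
    return out


def _call_from_orientations(orients: Iterable[Orientation]) -> Call:
    s = set(orients)
    if not s:
        return Call.NONE
    if s == {Orientation.SENSE}:
        return Call.SENSE_ONLY
    if s == {Orientation.ANTISENSE}:
        return Call.ANTISENSE_ONLY
    return Call.BIDIRECTIONAL


def classify_directionality(locus: Locus, tier: Tier | str) -> DirectionalityCall:
    """Classify a locus's transcription direction at one evidence tier.

    A tier is bidirectional iff it has at least one sense and one antisense
    supporting partner. The combined cDNA-and-EST tier requires the condition
    to hold in both single tiers independently; loci whose two tiers disagree
    (for example sense-only cDNA but bidirectional EST) are called ``none``.
    """
    tier = Tier(tier)
    if tier is Tier.CDNA_AND_EST:
        c1 = classify_directionality(locus, Tier.CDNA).call
        c2 = classify_directionality(locus, Tier.EST).call
        call = c1 if (c1 == c2 and c1 is not Call.NONE) else Call.NONE
    else:
        call = _call_from_orientations(
            a.orientation for a in locus.evidence.get(tier, [])
        )
    return DirectionalityCall(locus_id=locus.locus_id, tier=tier, call=call)


def high_confidence_loci(loci: Sequence[Locus]) -> list[Locus]:
    """Loci bidirectionally supported by both full-length cDNAs and ESTs."""
    return [
        l
        for l in loci
        if classify_directionality(l, Tier.CDNA_AND_EST).call is Call.BIDIRECTIONAL
    ]


def high_confidence_total(n_multi_block: int, n_single_block: int) -> int:
    """Total unique high-confidence loci from the multi- and single-block counts."""
    return n_multi_block + n_single_block


@dataclass
class PipelineRun:
    """One pseudogene-set x lncRNA-set run with its evidence tiers."""

    pseudogene_set: str
    lncrna_set: str
    anchored: list[Locus]
    cdna_tier: list[Locus]
    est_tier: list[Locus]

    @property
    def both_tier(self) -> list[Locus]:
        cdna_ids = {l.locus_id for l in self.cdna_tier}
        return [l for l in self.est_tier if l.locus_id in cdna_ids]


def run_pipeline(
    pseudogenes: Sequence[GeneModel],
    lncrnas: Sequence[GeneModel],
    cdnas: Sequence[GeneModel],
    ests: Sequence[GeneModel],
    pseudogene_set: str = "pseudogenes",
    lncrna_set: str = "lncRNAs",
    te_exclusion: str = "overlap",
) -> PipelineRun:
    """Execute the full chained intersection for one pseudogene/lncRNA pair."""
    anchored = anchor_loci(pseudogenes, lncrnas, te_exclusion=te_exclusion)
    cdna_tier = chain_evidence(anchored, cdnas, Tier.CDNA, te_exclusion=te_exclusion)
    est_tier = chain_evidence(anchored, ests, Tier.EST, te_exclusion=te_exclusion)
    logger.info(
        "run %s x %s: %d anchored, %d cDNA-tier, %d EST-tier loci",
        pseudogene_set,
        lncrna_set,
        len(anchored),
        len(cdna_tier),
        len(est_tier),
    )
    return PipelineRun(
        pseudogene_set=pseudogene_set,
        lncrna_set=lncrna_set,
        anchored=anchored,
        cdna_tier=cdna_tier,
        est_tier=est_tier,
    )


def _orientation_partition(loci_partners: list[list[Orientation]]) -> tuple[int, int, int, int]:
    total = len(loci_partners)
    sense = sum(1 for o in loci_partners if set(o) == {Orientation.SENSE})
    anti = sum(1 for o in loci_partners if set(o) == {Orientation.ANTISENSE})
    complex_ = total - sense - anti
    return total, sense, anti, complex_


def summarize(runs: Sequence[PipelineRun]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersection-count table and directionality matrix for a set of runs.

    The first table has one row per run and evidence tier with columns
    ``exon_exon_gene_ids`` / ``sense_overlaps`` / ``antisense_overlaps`` /
    ``complex_loci``: loci whose partners (lncRNA partners for the base row,
    tier evidence partners otherwise, pseudogene-relative) are all sense, all
    antisense, or mixed. The three categories partition every row's total.

    The second table is the 3 x 3 directionality matrix: counts of
    bidirectional / antisense-only / sense-only loci under cDNA, EST, and
    both-tiers-independently support, pooled over all runs on distinct locus
    IDs.
    """
    rows = []
    for run in runs:
        def orient_lists(loci: list[Locus], tiers: list[Tier] | None) -> list[list[Orientation]]:
            out = []
            for l in loci:
                if tiers is None:
                    out.append([a.orientation for a in l.lncrna])
                else:
                    out.append(
                        [a.orientation for t in tiers for a in l.evidence.get(t, [])]
                    )
            return out

        for label, loci, tiers in [
            ("lncRNA", run.anchored, None),
            ("cDNA", run.cdna_tier, [Tier.CDNA]),
            ("EST", run.est_tier, [Tier.EST]),
            ("cDNA and EST", run.both_tier, [Tier.CDNA, Tier.EST]),
        ]:
            total, sense, anti, complex_ = _orientation_partition(
                orient_lists(loci, tiers)
            )
            rows.append(
                {
                    "pseudogene_set": run.pseudogene_set,
                    "lncrna_set": run.lncrna_set,
                    "tier": label,
                    "exon_exon_gene_ids": total,
                    "sense_overlaps": sense,
                    "antisense_overlaps": anti,
                    "complex_loci": complex_,
                }
            )
    table1 = pd.DataFrame(rows)

    # directionality matrix over distinct locus IDs pooled across runs
    seen: dict[tuple[str, str], Call] = {}
    for run in runs:
        for tier, loci in [
            (Tier.CDNA, run.cdna_tier),
            (Tier.EST, run.est_tier),
            (Tier.CDNA_AND_EST, run.both_tier),
        ]:
            for l in loci:
                key = (tier.value, l.locus_id)
                if key not in seen:
                    seen[key] = classify_directionality(l, tier).call
    matrix_rows = []
    for tier in (Tier.CDNA, Tier.EST, Tier.CDNA_AND_EST):
        calls = [c for (t, _), c in seen.items() if t == tier.value]
        matrix_rows.append(
            {
                "support_from": tier.value,
                "bidirectional": sum(c is Call.BIDIRECTIONAL for c in calls),
                "antisense_only": sum(c is Call.ANTISENSE_ONLY for c in calls),
                "sense_only": sum(c is Call.SENSE_ONLY for c in calls),
            }
        )
    table2 = pd.DataFrame(matrix_rows)
    return table1, table2


def write_annotated_gtf(loci: Sequence[Locus], path: str | Path) -> None:
    """Write one annotated GTF line per focal pseudogene gene ID.

    The line carries the original first eight GTF columns over the gene span;
    retained exons are serialized in a ``retained_exons`` attribute
    (``start-end`` comma-joined) and every partner as
    ``(partnerID:SS:orientation:EE)`` with scores rounded to 4 decimals —
    lncRNA partners under ``intersects``, evidence partners under
    ``cdna_support`` / ``est_support``. The file re-parses under ``read_gtf``
    and fully round-trips under ``read_annotated_gtf``.
    """
    path = Path(path)
    ordered = sorted(loci, key=lambda l: (l.model.chrom, l.model.span.start, l.locus_id))
    with path.open("w") as fh:
        for locus in ordered:
            m = locus.model
            span = m.span
            attrs = {
                "gene_id": m.gene_id,
                "transcript_id": sorted(m.transcript_ids)[0]
                if m.transcript_ids
                else m.gene_id,
            }
            attrs.update(locus.original.attributes)
            attrs["retained_exons"] = ",".join(
                f"{e.start}-{e.end}" for e in m.exons
            )
            attrs["intersects"] = "".join(a.serialize() for a in locus.lncrna)
            for tier, key in ((Tier.CDNA, "cdna_support"), (Tier.EST, "est_support")):
                anns = locus.evidence.get(tier)
                if anns:
                    attrs[key] = "".join(a.serialize() for a in anns)
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        m.source,
                        "exon",
                        str(span.start),
                        str(span.end),
                        ".",
                        span.strand.value,
                        ".",
                        format_attributes(attrs),
                    ]
                )
                + "\n"
            )


def _parse_partner_groups(blob: str) -> list[IntersectAnnotation]:
    anns = []
    for group in blob.strip("()").split(")(") if blob else []:
        pid, ss, orient, ee = group.split(":")
        anns.append(
            IntersectAnnotation(
                partner_gene_id=pid,
                SS=float(ss),
                orientation=Orientation(orient),
                EE=float(ee),
            )
        )
    return anns


def read_annotated_gtf(path: str | Path, source_tag: str = "annotated") -> list[Locus]:
    """Re-load loci written by :func:`write_annotated_gtf`."""
    loci = []
    for m in read_gtf(path, source_tag):
        exon_blob = m.attributes.pop("retained_exons", "")
        if exon_blob:
            strand = m.strand
            chrom = m.chrom
            exons = [
                GenomicInterval(chrom, int(s.split("-")[0]), int(s.split("-")[1]), strand)
                for s in exon_blob.split(",")
            ]
        else:
            exons = m.exons
        lnc = _parse_partner_groups(m.attributes.pop("intersects", ""))
        evidence = {}
        for tier, key in ((Tier.CDNA, "cdna_support"), (Tier.EST, "est_support")):
            blob = m.attributes.pop(key, "")
            if blob:
                evidence[tier] = _parse_partner_groups(blob)
        model = m.with_exons(exons)
        loci.append(Locus(model=model, original=m, lncrna=lnc, evidence=evidence))
    return loci
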