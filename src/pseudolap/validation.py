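"""End-to-end consistency checks of the pipeline against planted fixtures.

Runs the full chained pipeline on a synthetic fixture and compares every
observable — surviving loci, retained exons, partner identities,
orientations and scores, per-tier directionality calls, the high-confidence
set, piRNA support flags, and SNP proximity hits — against the fixture's
truth table. Used by the test suite and by QC scripts.
"""

from __future__ import annotations

import math

from .annotation_io import normalize_est_models
from .fixtures import Fixture, LocusTruth, PartnerTruth
from .models import Call, PointFeature, Tier
from .overlays import pirna_support, snp_proximity
from .pipeline import classify_directionality, high_confidence_loci, run_pipeline


def _partners_match(
    got: list, expected: list[PartnerTruth], mismatches: list[str], label: str
) -> None:
    got_map = {a.partner_gene_id: a for a in got}
    exp_map = {p.partner_id: p for p in expected}
    if set(got_map) != set(exp_map):
        mismatches.append(
            f"{label}: partner IDs {sorted(got_map)} != {sorted(exp_map)}"
        )
        return
    for pid, exp in exp_map.items():
        ann = got_map[pid]
        if ann.orientation.value != exp.orientation:
            mismatches.append(f"{label}/{pid}: orientation {ann.orientation.value}")
        if not math.isclose(ann.SS, exp.SS, abs_tol=1e-9):
            mismatches.append(f"{label}/{pid}: SS {ann.SS} != {exp.SS}")
        if not math.isclose(ann.EE, exp.EE, abs_tol=1e-9):
            mismatches.append(f"{label}/{pid}: EE {ann.EE} != {exp.EE}")


def check_fixture_pipeline(fixture: Fixture) -> dict:
    """Run the pipeline on a fixture and diff every output against its truth.

    Returns a report dict with ``n_planted``, ``n_recovered``, and a
    ``mismatches`` list (empty when the pipeline reproduces the planted truth
    exactly).
    """
    mismatches: list[str] = []
    ests = normalize_est_models(fixture.ests_raw)
    run = run_pipeline(
        fixture.pseudogenes, fixture.lncrnas, fixture.cdnas, ests
    )
    truth_by_id: dict[str, LocusTruth] = {t.locus_id: t for t in fixture.truth}
    expected_ids = {t.locus_id for t in fixture.truth if t.in_exon_output}
    got_ids = {l.locus_id for l in run.anchored}
    if got_ids != expected_ids:
        mismatches.append(
            f"anchored loci {sorted(got_ids)} != expected {sorted(expected_ids)}"
        )

    loci_by_id = {l.locus_id: l for l in run.anchored}
    for lid in got_ids & expected_ids:
        locus, t = loci_by_id[lid], truth_by_id[lid]
        got_exons = [(e.start, e.end) for e in locus.model.exons]
        if got_exons != t.retained_exons:
            mismatches.append(f"{lid}: retained exons {got_exons} != {t.retained_exons}")
        _partners_match(locus.lncrna, t.lnc_partners, mismatches, f"{lid}/lnc")
        _partners_match(
            locus.evidence.get(Tier.CDNA, []), t.cdna_partners, mismatches,
            f"{lid}/cdna",
        )
        _partners_match(
            locus.evidence.get(Tier.EST, []), t.est_partners, mismatches,
            f"{lid}/est",
        )
        for tier, expected_call in (
            (Tier.CDNA, t.cdna_call),
            (Tier.EST, t.est_call),
            (Tier.CDNA_AND_EST, t.both_call),
        ):
            got_call = classify_directionality(locus, tier).call
            if got_call is not Call(expected_call):
                mismatches.append(
                    f"{lid}/{tier.value}: call {got_call.value} != {expected_call}"
                )

    hc_got = {l.locus_id for l in high_confidence_loci(run.anchored)}
    hc_expected = {t.locus_id for t in fixture.truth if t.high_confidence}
    if hc_got != hc_expected:
        mismatches.append(f"high-confidence {sorted(hc_got)} != {sorted(hc_expected)}")
    any_evidence = {l.locus_id for l in run.cdna_tier} | {
        l.locus_id for l in run.est_tier
    }
    if not hc_got <= any_evidence:
        mismatches.append("high-confidence set is not a subset of any-evidence set")

    pirna_feats = [
        PointFeature(feature_id=pid, chrom=chrom, start=s, end=e)
        for pid, chrom, s, e in fixture.pirnas
    ]
    records, _ = pirna_support(run.anchored, pirna_feats)
    support_by_id = {r.locus_id: r for r in records}
    for lid in got_ids & expected_ids:
        t = truth_by_id[lid]
        r = support_by_id[lid]
        if r.supported != t.pirna_supported or set(r.pirna_ids) != set(t.pirna_ids):
            mismatches.append(
                f"{lid}: piRNA support {sorted(r.pirna_ids)} != {sorted(t.pirna_ids)}"
            )

    snp_feats = [
        PointFeature(feature_id=rsid, chrom=chrom, start=pos, end=pos, payload=trait)
        for rsid, chrom, pos, trait in fixture.snps
    ]
    hits = snp_proximity(run.anchored, snp_feats, window=fixture.spec.snp_window)
    hits_by_locus: dict[str, set[str]] = {}
    inside_by_locus: dict[str, set[str]] = {}
    for h in hits:
        hits_by_locus.setdefault(h.locus_id, set()).add(h.rs_id)
        if h.inside_span:
            inside_by_locus.setdefault(h.locus_id, set()).add(h.rs_id)
    for lid in got_ids & expected_ids:
        t = truth_by_id[lid]
        if hits_by_locus.get(lid, set()) != set(t.snp_ids_window):
            mismatches.append(
                f"{lid}: SNP window hits {sorted(hits_by_locus.get(lid, set()))} "
                f"!= {sorted(t.snp_ids_window)}"
            )
        if inside_by_locus.get(lid, set()) != set(t.snp_ids_inside):
            mismatches.append(f"{lid}: inside-span SNP hits differ")

    return {
        "n_planted": len(fixture.truth),
        "n_expected_recovered": len(expected_ids),
        "n_recovered": len(got_ids),
        "mismatches": mismatches,
    }
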