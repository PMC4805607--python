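"""piRNA exonic support, GWAS-SNP proximity, and enrichment statistics.

A locus counts as piRNA-supported when any of its retained exons shares at
least one base with a piRNA interval — a piRNA inside the span but wholly
intronic does not count. Disease-associated SNPs are annotated when they fall
inside a locus span or within a window (default 10 kb, inclusive at both
boundaries) of either end. Support proportions between two locus sets are
compared with a pooled-variance two-proportion z-test, one-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import math

from intervaltree import IntervalTree
from scipy.stats import norm

from .models import GeneModel, PointFeature
from .pipeline import Locus


@dataclass(frozen=True)
class PirnaSupport:
    """Per-locus piRNA support: distinct piRNA IDs overlapping retained exons."""

    locus_id: str
    supported: bool
    pirna_ids: frozenset[str]

    @property
    def pirna_count(self) -> int:
        return len(self.pirna_ids)


@dataclass(frozen=True)
class SnpProximityHit:
    """A SNP inside a locus span or within the proximity window of it."""

    locus_id: str
    rs_id: str
    distance: int  # 0 when inside the span
    inside_span: bool
    payload: str = ""


@dataclass(frozen=True)
class TwoProportionResult:
    x1: int
    n1: int
    x2: int
    n2: int
    p1_hat: float
    p2_hat: float
    z: float
    p_one_tailed: float
    direction: str


def _exons_of(locus: Locus | GeneModel) -> tuple[str, list]:
    model = locus.model if isinstance(locus, Locus) else locus
    return model.gene_id, model.exons


def pirna_support(
    loci: Sequence[Locus | GeneModel], pirnas: Sequence[PointFeature]
) -> tuple[list[PirnaSupport], dict[str, float]]:
    """Flag loci whose retained exons share >= 1 bp with >= 1 piRNA.

    Returns the per-locus records plus aggregates: the supported-locus count
    and the mean number of distinct piRNA IDs per supported locus (the mean
    is over supported loci only).
    """
    trees: dict[str, IntervalTree] = {}
    for p in pirnas:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end + 1, p.feature_id)
    records = []
    for locus in loci:
        locus_id, exons = _exons_of(locus)
        ids: set[str] = set()
        for exon in exons:
            tree = trees.get(exon.chrom)
            if tree is None:
                continue
            ids.update(iv.data for iv in tree.overlap(exon.start, exon.end + 1))
        records.append(
            PirnaSupport(
                locus_id=locus_id, supported=bool(ids), pirna_ids=frozenset(ids)
            )
        )
    supported = [r for r in records if r.supported]
    aggregates = {
        "supported_count": float(len(supported)),
        "mean_pirna_count": (
            sum(r.pirna_count for r in supported) / len(supported)
            if supported
            else 0.0
        ),
    }
    return records, aggregates


def snp_proximity(
    loci: Sequence[Locus | GeneModel],
    snps: Sequence[PointFeature],
    window: int = 10_000,
) -> list[SnpProximityHit]:
    """SNPs inside a locus span or within ``window`` bp of either end.

    A SNP at exactly ``span.end + window`` (or ``span.start - window``) is a
    hit: the window is inclusive at both boundaries. With ``window=0`` only
    inside-span SNPs are returned. Distance is 0 inside the span, else the
    gap to the nearer span end.
    """
    hits = []
    for locus in loci:
        # proximity is measured against the gene's full span, not the
        # retained exons, so Locus inputs use the original model
        model = locus.original if isinstance(locus, Locus) else locus
        span = model.span
        for snp in snps:
            if snp.chrom != span.chrom:
                continue
            pos = snp.position
            if pos < span.start - window or pos > span.end + window:
                continue
            inside = span.start <= pos <= span.end
            distance = 0 if inside else min(
                abs(pos - span.start), abs(pos - span.end)
            )
            hits.append(
                SnpProximityHit(
                    locus_id=model.gene_id,
                    rs_id=snp.feature_id,
                    distance=distance,
                    inside_span=inside,
                    payload=snp.payload,
                )
            )
    return hits


def two_proportion_ztest(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    direction: str = "less",
    z_decimals: int | None = None,
) -> TwoProportionResult:
    """Pooled-variance two-proportion z-test, one-tailed.

    ``z = (x1/n1 - x2/n2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with the pooled
    ``p = (x1+x2)/(n1+n2)``; no continuity correction. The one-tailed p-value
    is the standard-normal tail in the declared direction (``less``: lower
    tail, ``greater``: upper tail). ``z_decimals`` rounds z before the tail
    lookup, reproducing the classic z-table convention of reading the tail at
    the statistic's printed precision.

    Raises ``ValueError`` when either sample size is zero; when the pooled
    proportion is exactly 0 or 1 the statistic is undefined and z and p are
    returned as NaN.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("two_proportion_ztest: both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("two_proportion_ztest: counts must satisfy 0 <= x <= n")
    if direction not in ("less", "greater"):
        raise ValueError(f"unknown direction {direction!r}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        z = p_val = float("nan")
    else:
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (p1 - p2) / se
        z_for_tail = round(z, z_decimals) if z_decimals is not None else z
        p_val = float(norm.cdf(z_for_tail) if direction == "less" else norm.sf(z_for_tail))
    return TwoProportionResult(
        x1=x1, n1=n1, x2=x2, n2=n2,
        p1_hat=p1, p2_hat=p2, z=z, p_one_tailed=p_val, direction=direction,
    )


def proportion_percent(x: int, n: int) -> float:
    """``100 * x / n`` with half-up rounding to 2 decimals."""
    if n < 1:
        raise ValueError("proportion_percent: n must be >= 1")
    pct = Decimal(100 * x) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
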