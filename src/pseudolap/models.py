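"""Core domain types shared across the package.

Coordinates are 1-based inclusive throughout (GTF convention); BED inputs are
converted on read. A gene "span" is derived from its exons, so annotation sets
without transcript-typed rows still load.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval on one strand.

    ``start`` and ``end`` are 1-based inclusive base-pair coordinates, so the
    interval length is ``end - start + 1`` and is always at least 1.
    """

    chrom: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def flipped(self) -> "GenomicInterval":
        return replace(self, strand=self.strand.flipped())


@dataclass
class GeneModel:
    """One annotated gene: ID, span, exon set, and its source annotation set.

    Invariants: all exons share chrom and strand with the span; the span covers
    every exon; the exon list is non-empty and sorted by start.
    """

    gene_id: str
    transcript_ids: frozenset[str]
    source: str
    exons: list[GenomicInterval]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: exons on multiple chromosomes/strands "
                f"({sorted(chroms)}, {sorted(s.value for s in strands)})"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))

    @property
    def span(self) -> GenomicInterval:
        """Genomic span: min exon start to max exon end."""
        return GenomicInterval(
            self.chrom,
            self.exons[0].start,
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> Strand:
        return self.exons[0].strand

    def with_strand_flipped(self) -> "GeneModel":
        return GeneModel(
            gene_id=self.gene_id,
            transcript_ids=self.transcript_ids,
            source=self.source,
            exons=[e.flipped() for e in self.exons],
            attributes=dict(self.attributes),
        )

    def with_exons(self, exons: list[GenomicInterval]) -> "GeneModel":
        return GeneModel(
            gene_id=self.gene_id,
            transcript_ids=self.transcript_ids,
            source=self.source,
            exons=list(exons),
            attributes=dict(self.attributes),
        )


class ReadEnd(str, enum.Enum):
    """Which end of the transcript an EST was sequenced from."""

    FIVE_PRIME = "5prime"
    THREE_PRIME = "3prime"
    UNKNOWN = "unknown"


@dataclass
class EstRecord:
    """An EST gene model plus its read-end metadata.

    3' ESTs are conventionally reported on the strand opposite the transcript;
    orientation normalization flips them back.
    """

    model: GeneModel
    read_end: ReadEnd


class Orientation(str, enum.Enum):
    """Relative strandedness of two overlapping genes."""

    SENSE = "sense"
    ANTISENSE = "antisense"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class OverlapScore:
    """Quantitative overlap of a gene pair.

    ``P1``/``P2`` are the reciprocal span coverage fractions; ``SS = P1 * P2``
    is the span-span score. ``exon_pair_scores`` holds one entry per exon pair
    with positive overlap as ``(exon1_index, exon2_index, E)`` where ``E`` is
    the product of the two per-exon coverage fractions. ``TE`` is the number of
    gene-1 exons plus the gene-2 exons overlapping no gene-1 exon, and
    ``EE = sum(E) / TE``. All scores lie in [0, 1]; EE is defined relative to
    gene 1 (the pipeline always anchors on the pseudogene).
    """

    P1: float
    P2: float
    SS: float
    exon_pair_scores: tuple[tuple[int, int, float], ...]
    TE: int
    EE: float


@dataclass(frozen=True)
class IntersectAnnotation:
    """Per-partner record appended to a focal gene.

    Serialized as ``(partnerID:SS:orientation:EE)`` with scores rounded to 4
    decimals; SS is positive for every recorded annotation.
    """

    partner_gene_id: str
    SS: float
    orientation: Orientation
    EE: float

    def serialize(self) -> str:
        return (
            f"({self.partner_gene_id}:{self.SS:.4f}:"
            f"{self.orientation.value}:{self.EE:.4f})"
        )


class Tier(str, enum.Enum):
    """Transcription-evidence tier of a directionality call."""

    CDNA = "cDNA"
    EST = "EST"
    CDNA_AND_EST = "cDNA_and_EST"


class Call(str, enum.Enum):
    SENSE_ONLY = "sense_only"
    ANTISENSE_ONLY = "antisense_only"
    BIDIRECTIONAL = "bidirectional"
    NONE = "none"


@dataclass(frozen=True)
class DirectionalityCall:
    """Per-locus transcription-direction classification at one evidence tier."""

    locus_id: str
    tier: Tier
    call: Call


@dataclass
class LocusCluster:
    """A set of positionally overlapping gene models plus its representative.

    Members are single-linkage connected through span overlaps; the
    representative is the member with the lowest span start (input order
    breaks ties).
    """

    members: list[GeneModel]
    representative: GeneModel
    provenance: frozenset[str]


@dataclass(frozen=True)
class PointFeature:
    """A point-like feature (piRNA anchor, SNP) in 1-based coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    payload: str = ""

    @property
    def position(self) -> int:
        return self.start
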