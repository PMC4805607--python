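from __future__ import annotations

import pytest
from hypothesis import strategies as st

from pseudolap.models import GeneModel, GenomicInterval, Strand


def make_gene(
    gene_id: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    source: str = "test",
    transcripts: set[str] | None = None,
    **attrs: str,
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        transcript_ids=frozenset(transcripts or {f"{gene_id}.t1"}),
        source=source,
        exons=[GenomicInterval(chrom, s, e, Strand(strand)) for s, e in exons],
        attributes=dict(attrs),
    )


@pytest.fixture
def gene_factory():
    return make_gene


@st.composite
def gene_models(draw, chrom: str = "chr1", max_coord: int = 500):
    """Random small gene: 1-4 disjoint sorted exons within [1, max_coord]."""
    n_exons = draw(st.integers(1, 4))
    cursor = draw(st.integers(1, 50))
    exons = []
    for _ in range(n_exons):
        length = draw(st.integers(1, 60))
        exons.append((cursor, cursor + length - 1))
        cursor += length + draw(st.integers(1, 40))
        if cursor > max_coord:
            break
    strand = draw(st.sampled_from(["+", "-"]))
    gid = f"G{draw(st.integers(0, 10**6))}"
    return make_gene(gid, exons, strand=strand, chrom=chrom)
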