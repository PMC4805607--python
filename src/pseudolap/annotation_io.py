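"""Reading and writing of GTF/BED/TSV annotation inputs.

GTF is the primary dialect: 9 tab-delimited columns with 1-based inclusive
coordinates and ``gene_id "X"; transcript_id "Y";`` attributes. Exon-typed rows
are grouped by ``gene_id`` into :class:`~pseudolap.models.GeneModel` objects;
the gene span is derived from the exons. BED intervals (0-based half-open) and
SNP tables are converted to the internal 1-based inclusive convention on read.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

from .models import (
    EstRecord,
    GeneModel,
    GenomicInterval,
    PointFeature,
    ReadEnd,
    Strand,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfFormatError(ValueError):
    """A malformed GTF line; the message names the offending line number."""


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def format_attributes(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def read_gtf(path: str | Path, source_tag: str) -> list[GeneModel]:
    """Read a GTF file and assemble one :class:`GeneModel` per ``gene_id``.

    Only ``exon``-typed rows contribute coordinates; transcript rows and any
    other feature types are ignored (spans are derived from exons so sets
    lacking transcript rows still load). If a single ``gene_id`` places exons
    on more than one chromosome or strand it is split into per-chrom/strand
    models with ``gene_id#chrom#strand`` suffixed IDs, since the overlap
    scores presume a single span.

    Raises
    ------
    GtfFormatError
        On a wrong column count, ``start > end``, an unknown strand symbol,
        or a missing ``gene_id`` attribute; the message carries the 1-based
        line number.
    """
    path = Path(path)
    # (gene_id, chrom, strand) -> accumulating exon/transcript/attr state
    groups: "OrderedDict[tuple[str, str, str], dict]" = OrderedDict()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfFormatError(
                    f"{path}:{lineno}: expected 9 tab-delimited columns, "
                    f"got {len(cols)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand_s, _frame, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfFormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start > end:
                raise GtfFormatError(f"{path}:{lineno}: start {start} > end {end}")
            if strand_s not in ("+", "-"):
                raise GtfFormatError(
                    f"{path}:{lineno}: unknown strand symbol {strand_s!r}"
                )
            attrs = _parse_attributes(attr_s)
            if "gene_id" not in attrs:
                raise GtfFormatError(f"{path}:{lineno}: missing gene_id attribute")
            if feature not in ("exon", "transcript"):
                continue
            key = (attrs["gene_id"], chrom, strand_s)
            state = groups.setdefault(
                key, {"exons": [], "transcripts": set(), "attrs": {}}
            )
            if "transcript_id" in attrs:
                state["transcripts"].add(attrs["transcript_id"])
            for k, v in attrs.items():
                if k not in ("gene_id", "transcript_id"):
                    state["attrs"].setdefault(k, v)
            if feature == "exon":
                state["exons"].append(
                    GenomicInterval(chrom, start, end, Strand(strand_s))
                )

    # split genes spread over several chrom/strand groups with suffixed IDs
    per_gene: dict[str, int] = {}
    for gene_id, _, _ in groups:
        per_gene[gene_id] = per_gene.get(gene_id, 0) + 1

    models: list[GeneModel] = []
    for (gene_id, chrom, strand_s), state in groups.items():
        if not state["exons"]:
            continue
        out_id = gene_id
        if per_gene[gene_id] > 1:
            out_id = f"{gene_id}#{chrom}#{strand_s}"
            logger.warning(
                "gene %s spans multiple chrom/strand groups; split as %s",
                gene_id,
                out_id,
            )
        models.append(
            GeneModel(
                gene_id=out_id,
                transcript_ids=frozenset(state["transcripts"]),
                source=source_tag,
                exons=state["exons"],
                attributes=state["attrs"],
            )
        )
    return models


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as exon-typed GTF rows (round-trips under read_gtf)."""
    path = Path(path)
    with path.open("w") as fh:
        for m in models:
            tids = sorted(m.transcript_ids) or [m.gene_id]
            base = {"gene_id": m.gene_id, "transcript_id": tids[0]}
            base.update(m.attributes)
            for exon in m.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            m.source,
                            "exon",
                            str(exon.start),
                            str(exon.end),
                            ".",
                            exon.strand.value,
                            ".",
                            format_attributes(base),
                        ]
                    )
                    + "\n"
                )


def deduplicate_ids(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop entries sharing gene ID and transcript-ID set; keep first in order.

    Idempotent; the number of removals is logged.
    """
    seen: set[tuple[str, frozenset[str]]] = set()
    out: list[GeneModel] = []
    for m in models:
        key = (m.gene_id, m.transcript_ids)
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
    removed = len(models) - len(out)
    if removed:
        logger.info("deduplicate_ids: removed %d redundant entries", removed)
    return out


def normalize_est_orientation(est: EstRecord) -> GeneModel:
    """Flip the strand of a 3' EST to its biological transcription direction.

    3' ESTs are reported on the strand opposite the transcript they came
    from, so their stated orientation is reverted; 5' and unknown-end records
    pass through unchanged. Coordinates are never touched and the flip is
    involutive.
    """
    if est.read_end is ReadEnd.THREE_PRIME:
        return est.model.with_strand_flipped()
    return est.model


def normalize_est_models(
    models: Iterable[GeneModel], read_end_attr: str = "read_end"
) -> list[GeneModel]:
    """Normalize a batch of EST models using a read-end attribute.

    The read end is taken from the attribute named ``read_end_attr``
    (values ``5prime``/``3prime``; anything else is treated as unknown).
    """
    out = []
    for m in models:
        raw = m.attributes.get(read_end_attr, "unknown")
        try:
            end = ReadEnd(raw)
        except ValueError:
            end = ReadEnd.UNKNOWN
        out.append(normalize_est_orientation(EstRecord(model=m, read_end=end)))
    return out


def load_ests(
    path: str | Path, source_tag: str = "EST", read_end_attr: str = "read_end"
) -> list[GeneModel]:
    """Read an EST GTF and normalize 3'-read orientations in one pass."""
    return normalize_est_models(read_gtf(path, source_tag), read_end_attr)


def read_point_features(
    path: str | Path,
    format: str = "bed",
    columns: dict[str, int] | None = None,
) -> list[PointFeature]:
    """Read piRNA BED or SNP TSV records into 1-based point/interval features.

    BED is 0-based half-open and converted on read (a BED line
    ``chr1 99 100 pi1`` becomes position 100). For ``tsv``, ``columns`` maps
    the keys ``id``, ``chrom``, ``pos`` and optionally ``payload`` to 0-based
    column indices; the default layout is rsID/chrom/pos/trait.
    """
    path = Path(path)
    features: list[PointFeature] = []
    if format == "bed":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom, start0, end0 = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else f"{chrom}:{start0}-{end0}"
                features.append(
                    PointFeature(
                        feature_id=name,
                        chrom=chrom,
                        start=start0 + 1,
                        end=end0,
                        payload=cols[4] if len(cols) > 4 else "",
                    )
                )
    elif format == "tsv":
        cmap = columns or {"id": 0, "chrom": 1, "pos": 2, "payload": 3}
        for key in ("id", "chrom", "pos"):
            if key not in cmap:
                raise ValueError(f"TSV column mapping missing required key {key!r}")
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                try:
                    fid = cols[cmap["id"]]
                    chrom = cols[cmap["chrom"]]
                    pos = int(cols[cmap["pos"]])
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"{path}:{lineno}: column mapping {cmap} does not fit "
                        f"row with {len(cols)} columns"
                    ) from exc
                payload = ""
                if "payload" in cmap and cmap["payload"] < len(cols):
                    payload = cols[cmap["payload"]]
                features.append(
                    PointFeature(
                        feature_id=fid, chrom=chrom, start=pos, end=pos,
                        payload=payload,
                    )
                )
    else:
        raise ValueError(f"unknown point-feature format {format!r}")
    return features
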