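"""Synthetic annotation fixtures with planted overlap structure.

Emulates the input ecosystem of a pseudogene/lncRNA intersection study at
desk scale: a pseudogene GTF, a lncRNA GTF, full-length cDNA and EST GTFs
(ESTs carry a ``read_end`` attribute, and 3'-read records are emitted on the
biologically wrong strand so orientation normalization is exercised), a
piRNA BED, a SNP TSV, and optionally three overlapping pseudogene "database"
catalogs for merge tests. Every planted locus follows an explicit directive
(partner orientations per evidence tier, exon count, piRNA and SNP
placement), and the generator returns a machine-readable truth table whose
expected scores are computed by per-base set arithmetic, independently of
the closed-form scoring used by the pipeline.

Loci are laid out on a toy genome of three chromosomes (1 Mb each) in
well-separated 40 kb slots, so no two planted loci interact positionally.
Same seed and spec give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .models import GeneModel, GenomicInterval, Strand

_CHROMS = ("chrA", "chrB", "chrC")
_SLOT = 40_000
_SLOTS_PER_CHROM = 1_000_000 // _SLOT

_ORIENT_CHOICES = ("sense", "antisense", "both", "none")


@dataclass(frozen=True)
class LocusDirective:
    """Planted structure for one pseudogene locus.

    ``lncrna`` / ``cdna`` / ``est`` give the orientation(s) of the partners
    overlapping the locus's shared exon: ``sense``, ``antisense``, ``both``
    (one of each), or ``none``. ``lncrna`` additionally admits ``intronic``
    (span overlap without exon overlap — the locus must then vanish from the
    exon-mode intersect). ``pirna`` places a piRNA on the shared exon
    (``exonic``), inside an intron (``intronic``), or nowhere; ``snp`` plants
    a SNP inside the span, just within the 10 kb window (``near``), outside
    it (``far``), or nowhere.
    """

    lncrna: str = "sense"
    cdna: str = "none"
    est: str = "none"
    n_exons: int = 3
    pirna: str = "none"
    snp: str = "none"

    def __post_init__(self) -> None:
        if self.lncrna not in _ORIENT_CHOICES + ("intronic",):
            raise ValueError(f"bad lncrna directive {self.lncrna!r}")
        for name in ("cdna", "est"):
            if getattr(self, name) not in _ORIENT_CHOICES:
                raise ValueError(f"bad {name} directive {getattr(self, name)!r}")
        if self.pirna not in ("exonic", "intronic", "none"):
            raise ValueError(f"bad pirna directive {self.pirna!r}")
        if self.snp not in ("inside", "near", "far", "none"):
            raise ValueError(f"bad snp directive {self.snp!r}")
        if self.lncrna in ("none", "intronic") and (
            self.cdna != "none" or self.est != "none"
        ):
            raise ValueError(
                "contradictory directive: evidence partners require an "
                "exon-overlapping lncRNA anchor"
            )
        if self.n_exons < 1 or self.n_exons > 5:
            raise ValueError("n_exons must be in 1..5")
        if self.lncrna == "intronic" and self.n_exons < 2:
            raise ValueError("intronic lncRNA placement needs >= 2 exons")
        if self.pirna == "intronic" and self.n_exons < 2:
            raise ValueError("intronic piRNA placement needs >= 2 exons")


@dataclass
class FixtureSpec:
    """Seeded recipe for one synthetic input set."""

    seed: int = 0
    directives: list[LocusDirective] = field(default_factory=list)
    n_decoy_lncrnas: int = 2
    est_3prime_fraction: float = 0.5
    snp_window: int = 10_000

    def __post_init__(self) -> None:
        if len(self.directives) > len(_CHROMS) * _SLOTS_PER_CHROM:
            raise ValueError("too many loci for the toy genome")


@dataclass
class PartnerTruth:
    partner_id: str
    orientation: str  # relative to the pseudogene
    SS: float
    EE: float


@dataclass
class LocusTruth:
    """Expected pipeline outcome for one planted locus."""

    locus_id: str
    directive: LocusDirective
    in_exon_output: bool
    retained_exons: list[tuple[int, int]]
    lnc_partners: list[PartnerTruth]
    cdna_partners: list[PartnerTruth]
    est_partners: list[PartnerTruth]
    cdna_call: str  # sense_only / antisense_only / bidirectional / none
    est_call: str
    both_call: str
    high_confidence: bool
    pirna_supported: bool
    pirna_ids: list[str]
    snp_ids_inside: list[str]
    snp_ids_window: list[str]


@dataclass
class Fixture:
    """In-memory fixture: gene model lists, features, and the truth table."""

    spec: FixtureSpec
    pseudogenes: list[GeneModel]
    lncrnas: list[GeneModel]
    cdnas: list[GeneModel]
    ests_raw: list[GeneModel]  # as written: 3' reads on the wrong strand
    ests_true: list[GeneModel]  # biological orientation
    pirnas: list[tuple[str, str, int, int]]  # (id, chrom, start, end) 1-based
    snps: list[tuple[str, str, int, str]]  # (rsid, chrom, pos, trait)
    truth: list[LocusTruth]


def _truth_scores(
    pg_exons: list[tuple[int, int]], partner_exons: list[tuple[int, int]]
) -> tuple[float, float]:
    """Per-base (set-arithmetic) span and exon scores, for the truth table."""
    span1 = set(range(pg_exons[0][0], max(e for _, e in pg_exons) + 1))
    span2 = set(
        range(partner_exons[0][0], max(e for _, e in partner_exons) + 1)
    )
    ov = len(span1 & span2)
    ss = (ov / len(span1)) * (ov / len(span2))
    total = 0.0
    shared2 = set()
    for i, (s1, e1) in enumerate(pg_exons):
        b1 = set(range(s1, e1 + 1))
        for j, (s2, e2) in enumerate(partner_exons):
            b2 = set(range(s2, e2 + 1))
            inter = len(b1 & b2)
            if inter:
                total += (inter / len(b1)) * (inter / len(b2))
                shared2.add(j)
    te = len(pg_exons) + len(partner_exons) - len(shared2)
    return ss, total / te


def _gene(
    gene_id: str,
    source: str,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    **attrs: str,
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        transcript_ids=frozenset({f"{gene_id}.t1"}),
        source=source,
        exons=[GenomicInterval(chrom, s, e, Strand(strand)) for s, e in exons],
        attributes=dict(attrs),
    )


def _orient_list(directive_value: str) -> list[str]:
    if directive_value == "both":
        return ["sense", "antisense"]
    if directive_value in ("sense", "antisense"):
        return [directive_value]
    return []


def _call(orients: list[str]) -> str:
    s = set(orients)
    if not s:
        return "none"
    if s == {"sense"}:
        return "sense_only"
    if s == {"antisense"}:
        return "antisense_only"
    return "bidirectional"


def generate(spec: FixtureSpec) -> Fixture:
    """Build the fixture in memory (see :func:`write_fixture` for files)."""
    rng = np.random.default_rng(spec.seed)
    pseudogenes: list[GeneModel] = []
    lncrnas: list[GeneModel] = []
    cdnas: list[GeneModel] = []
    ests_raw: list[GeneModel] = []
    ests_true: list[GeneModel] = []
    pirnas: list[tuple[str, str, int, int]] = []
    snps: list[tuple[str, str, int, str]] = []
    truth: list[LocusTruth] = []

    for li, d in enumerate(spec.directives):
        chrom = _CHROMS[li % len(_CHROMS)]
        slot_start = (li // len(_CHROMS)) * _SLOT + 1
        strand = "+" if rng.random() < 0.5 else "-"
        anti = "-" if strand == "+" else "+"

        # pseudogene exons inside the first 6 kb of the slot
        cursor = slot_start + int(rng.integers(200, 600))
        pg_exons: list[tuple[int, int]] = []
        for _ in range(d.n_exons):
            length = int(rng.integers(120, 400))
            pg_exons.append((cursor, cursor + length - 1))
            cursor += length + int(rng.integers(250, 700))
        pg_id = f"PG{li:04d}"
        pseudogenes.append(_gene(pg_id, "pseudogene", chrom, strand, pg_exons))

        target_idx = d.n_exons // 2
        ts, te_ = pg_exons[target_idx]

        def partner_exons_for(shift: int) -> list[tuple[int, int]]:
            # partial overlap of the target exon; shift < min intron (250)
            s = max(slot_start, ts + shift)
            e = te_ + shift
            return [(min(s, e), max(s, e))]

        lnc_partners: list[PartnerTruth] = []
        if d.lncrna == "intronic":
            # exon wholly inside the first intron: span overlap, no exon overlap
            gap_s, gap_e = pg_exons[0][1] + 1, pg_exons[1][0] - 1
            mid = (gap_s + gap_e) // 2
            lid = f"LNC{li:04d}a"
            lncrnas.append(
                _gene(lid, "lncRNA", chrom, strand, [(gap_s + 5, mid)])
            )
        else:
            for k, orient in enumerate(_orient_list(d.lncrna)):
                lid = f"LNC{li:04d}{chr(ord('a') + k)}"
                shift = int(rng.integers(-60, 61))
                exons = partner_exons_for(shift)
                lncrnas.append(
                    _gene(
                        lid, "lncRNA", chrom,
                        strand if orient == "sense" else anti, exons,
                    )
                )
                ss, ee = _truth_scores(pg_exons, exons)
                lnc_partners.append(PartnerTruth(lid, orient, ss, ee))

        in_output = bool(lnc_partners)
        retained = [pg_exons[target_idx]] if in_output else []

        cdna_partners: list[PartnerTruth] = []
        for k, orient in enumerate(_orient_list(d.cdna)):
            cid = f"CDNA{li:04d}{chr(ord('a') + k)}"
            shift = int(rng.integers(-60, 61))
            exons = partner_exons_for(shift)
            cdnas.append(
                _gene(
                    cid, "cDNA", chrom,
                    strand if orient == "sense" else anti, exons,
                )
            )
            ss, ee = _truth_scores(retained, exons)
            cdna_partners.append(PartnerTruth(cid, orient, ss, ee))

        est_partners: list[PartnerTruth] = []
        for k, orient in enumerate(_orient_list(d.est)):
            eid = f"EST{li:04d}{chr(ord('a') + k)}"
            shift = int(rng.integers(-60, 61))
            exons = partner_exons_for(shift)
            true_strand = strand if orient == "sense" else anti
            is_3prime = rng.random() < spec.est_3prime_fraction
            emitted_strand = (
                ("-" if true_strand == "+" else "+") if is_3prime else true_strand
            )
            read_end = "3prime" if is_3prime else "5prime"
            ests_raw.append(
                _gene(eid, "EST", chrom, emitted_strand, exons, read_end=read_end)
            )
            ests_true.append(
                _gene(eid, "EST", chrom, true_strand, exons, read_end=read_end)
            )
            ss, ee = _truth_scores(retained, exons)
            est_partners.append(PartnerTruth(eid, orient, ss, ee))

        pirna_ids: list[str] = []
        if d.pirna == "exonic":
            pid = f"PI{li:04d}"
            mid = (ts + te_) // 2
            pirnas.append((pid, chrom, max(ts, mid - 14), min(te_, mid + 15)))
            pirna_ids.append(pid)
        elif d.pirna == "intronic":
            gap_s, gap_e = pg_exons[0][1] + 1, pg_exons[1][0] - 1
            mid = (gap_s + gap_e) // 2
            pirnas.append((f"PI{li:04d}", chrom, mid - 10, mid + 10))

        span_s, span_e = pg_exons[0][0], max(e for _, e in pg_exons)
        snp_inside: list[str] = []
        snp_window_ids: list[str] = []
        if d.snp != "none":
            rsid = f"rs{900000 + li}"
            if d.snp == "inside":
                pos = (ts + te_) // 2
                snp_inside.append(rsid)
                snp_window_ids.append(rsid)
            elif d.snp == "near":
                pos = span_e + int(rng.integers(1, spec.snp_window + 1))
                snp_window_ids.append(rsid)
            else:  # far: outside the window but still inside the slot
                pos = span_e + spec.snp_window + int(rng.integers(1000, 5000))
            snps.append((rsid, chrom, pos, f"trait_{li}"))

        cdna_call = _call([p.orientation for p in cdna_partners]) if in_output else "none"
        est_call = _call([p.orientation for p in est_partners]) if in_output else "none"
        both_call = (
            cdna_call if (cdna_call == est_call and cdna_call != "none") else "none"
        )
        truth.append(
            LocusTruth(
                locus_id=pg_id,
                directive=d,
                in_exon_output=in_output,
                retained_exons=retained,
                lnc_partners=lnc_partners,
                cdna_partners=cdna_partners,
                est_partners=est_partners,
                cdna_call=cdna_call,
                est_call=est_call,
                both_call=both_call,
                high_confidence=(both_call == "bidirectional"),
                pirna_supported=bool(pirna_ids) and in_output,
                pirna_ids=pirna_ids,
                snp_ids_inside=snp_inside,
                snp_ids_window=snp_window_ids,
            )
        )

    # decoy lncRNAs overlapping nothing: placed in slots beyond the last locus
    for k in range(spec.n_decoy_lncrnas):
        idx = len(spec.directives) + k
        if idx >= len(_CHROMS) * _SLOTS_PER_CHROM:
            break
        chrom = _CHROMS[idx % len(_CHROMS)]
        start = (idx // len(_CHROMS)) * _SLOT + 1 + int(rng.integers(100, 1000))
        length = int(rng.integers(200, 2000))
        lncrnas.append(
            _gene(
                f"LNCDECOY{k:03d}", "lncRNA", chrom,
                "+" if rng.random() < 0.5 else "-",
                [(start, start + length - 1)],
            )
        )

    return Fixture(
        spec=spec,
        pseudogenes=pseudogenes,
        lncrnas=lncrnas,
        cdnas=cdnas,
        ests_raw=ests_raw,
        ests_true=ests_true,
        pirnas=pirnas,
        snps=snps,
        truth=truth,
    )


def random_spec(seed: int, n_loci: int = 12) -> FixtureSpec:
    """A randomized but valid directive set, for property-style testing."""
    rng = np.random.default_rng(seed)
    directives = []
    for _ in range(n_loci):
        lnc = str(rng.choice(["sense", "antisense", "both", "both", "none", "intronic"]))
        n_exons = int(rng.integers(2, 6))
        if lnc in ("none", "intronic"):
            cdna = est = "none"
        else:
            cdna = str(rng.choice(["sense", "antisense", "both", "none"]))
            est = str(rng.choice(["sense", "antisense", "both", "none"]))
        directives.append(
            LocusDirective(
                lncrna=lnc,
                cdna=cdna,
                est=est,
                n_exons=n_exons,
                pirna=str(rng.choice(["exonic", "intronic", "none"])),
                snp=str(rng.choice(["inside", "near", "far", "none"])),
            )
        )
    return FixtureSpec(seed=seed + 1, directives=directives)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as GTF/BED/TSV files plus a truth-table TSV."""
    from .annotation_io import write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pseudogenes": outdir / "pseudogenes.gtf",
        "lncrnas": outdir / "lncrnas.gtf",
        "cdnas": outdir / "cdnas.gtf",
        "ests": outdir / "ests.gtf",
        "pirnas": outdir / "pirnas.bed",
        "snps": outdir / "snps.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gtf(fixture.pseudogenes, paths["pseudogenes"])
    write_gtf(fixture.lncrnas, paths["lncrnas"])
    write_gtf(fixture.cdnas, paths["cdnas"])
    write_gtf(fixture.ests_raw, paths["ests"])
    with paths["pirnas"].open("w") as fh:
        for pid, chrom, start, end in fixture.pirnas:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{pid}\n")
    with paths["snps"].open("w") as fh:
        fh.write("#rsID\tchrom\tpos\ttrait\n")
        for rsid, chrom, pos, trait in fixture.snps:
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{trait}\n")
    with paths["truth"].open("w") as fh:
        fh.write(
            "locus_id\tin_exon_output\tretained_exons\tlnc_partners\t"
            "cdna_partners\test_partners\tcdna_call\test_call\tboth_call\t"
            "high_confidence\tpirna_supported\tpirna_ids\t"
            "snp_inside\tsnp_window\n"
        )
        for t in fixture.truth:
            fmt = lambda ps: ";".join(
                f"{p.partner_id}:{p.SS:.6f}:{p.orientation}:{p.EE:.6f}" for p in ps
            )
            fh.write(
                "\t".join(
                    [
                        t.locus_id,
                        str(int(t.in_exon_output)),
                        ",".join(f"{s}-{e}" for s, e in t.retained_exons),
                        fmt(t.lnc_partners),
                        fmt(t.cdna_partners),
                        fmt(t.est_partners),
                        t.cdna_call,
                        t.est_call,
                        t.both_call,
                        str(int(t.high_confidence)),
                        str(int(t.pirna_supported)),
                        ",".join(t.pirna_ids),
                        ",".join(t.snp_ids_inside),
                        ",".join(t.snp_ids_window),
                    ]
                )
                + "\n"
            )
    return paths


def generate_catalog_fixture(
    seed: int, n_loci: int = 30
) -> tuple[list[tuple[str, list[GeneModel]]], dict[tuple[str, ...], int]]:
    """Three overlapping pseudogene catalogs with a known Venn structure.

    Each planted locus is annotated by a random non-empty subset of the three
    databases, with small independent span jitter per database (accession
    synonyms of one locus). Returns the catalogs and the expected Venn-cell
    counts; the expected merged non-redundant count is ``n_loci``.
    """
    rng = np.random.default_rng(seed)
    tags = ("dbA", "dbB", "dbC")
    catalogs: dict[str, list[GeneModel]] = {t: [] for t in tags}
    venn: dict[tuple[str, ...], int] = {}
    for li in range(n_loci):
        chrom = _CHROMS[li % len(_CHROMS)]
        base = (li // len(_CHROMS)) * _SLOT + 1 + int(rng.integers(100, 2000))
        length = int(rng.integers(300, 4000))
        members = [t for t in tags if rng.random() < 0.6]
        if not members:
            members = [tags[int(rng.integers(0, 3))]]
        for t in members:
            jitter = int(rng.integers(0, min(200, length // 2)))
            catalogs[t].append(
                _gene(
                    f"{t}_PG{li:04d}", t, chrom,
                    "+" if rng.random() < 0.5 else "-",
                    [(base + jitter, base + length - 1 + jitter)],
                )
            )
        cell = tuple(sorted(members))
        venn[cell] = venn.get(cell, 0) + 1
    return [(t, catalogs[t]) for t in tags], venn
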