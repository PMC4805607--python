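# pseudolap

Scored genome-wide intersection of pseudogenes with long non-coding RNAs
(lncRNAs), strand-aware transcription-evidence classification, non-redundant
pseudogene catalog construction, and piRNA / disease-SNP overlay statistics.

Pseudogenes are genomic copies of genes that have lost protein-coding
ability, yet many are transcribed, and lncRNA transcription across a
pseudogene — especially antisense to it — can regulate the pseudogene, the
overlapping lncRNA, and the pseudogene's parental gene. `pseudolap` is for
regulatory genomicists who want to map that overlap space from standard
annotation files: it takes pseudogene, lncRNA, full-length cDNA and EST sets
as GTF, piRNAs as BED, and SNP catalogs as TSV, and produces scored,
orientation-annotated pseudogene–lncRNA loci with per-tier directionality
calls.

## The scores

For a gene pair with spans S1, S2 sharing `ov` bases, the span–span score is

    SS = P1 · P2,   P1 = ov/|S1|,   P2 = ov/|S2|

(1 for identical spans, 0 for disjoint). At exon level every exon pair with
a shared base contributes `E = (covered fraction of exon 1) · (covered
fraction of exon 2)`, and

    EE = Σ E / TE,   TE = #exons(gene 1) + #exons(gene 2 overlapping no gene-1 exon)

so identical exon structures score EE = 1. Orientation (sense/antisense,
relative to the pseudogene) is reported separately; overlap arithmetic
ignores strand. A locus is *bidirectional* at an evidence tier when it has
both sense and antisense partners there; the *high-confidence* set is
bidirectional in both the cDNA and the EST tier independently. Two support
proportions are compared with the pooled two-proportion one-tailed z-test

    z = (x1/n1 − x2/n2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2)),   p̂ = (x1+x2)/(n1+n2).

## Worked example

```python
from pseudolap import (anchor_loci, exon_exon_score, proportion_percent,
                       relative_orientation, span_span_score,
                       two_proportion_ztest, write_annotated_gtf)
from pseudolap.models import GeneModel, GenomicInterval, Strand

def gene(gid, exons, strand):
    return GeneModel(gid, frozenset({gid + ".t1"}), "demo",
                     [GenomicInterval("chr1", s, e, Strand(strand)) for s, e in exons])

pg  = gene("PSG1", [(1, 100), (201, 300)], "+")   # 2-exon pseudogene
lnc = gene("LNC1", [(51, 150)], "-")              # antisense lncRNA

p1, p2, ss = span_span_score(pg, lnc)
pairs, te, ee = exon_exon_score(pg, lnc)
print(f"P1={p1:.4f} P2={p2:.4f} SS={ss:.4f}")
print(f"TE={te} EE={ee:.4f}")
print("orientation:", relative_orientation(pg, lnc).value)

write_annotated_gtf(anchor_loci([pg], [lnc]), "demo.gtf")
print(open("demo.gtf").read().rstrip())
```

prints

```
P1=0.3333 P2=1.0000 SS=0.3333
TE=2 EE=0.1250
orientation: antisense
chr1	demo	exon	1	100	.	+	.	gene_id "PSG1"; transcript_id "PSG1.t1"; retained_exons "1-100"; intersects "(LNC1:0.3333:antisense:0.1250)";
```

The lncRNA covers one third of the pseudogene span (P1) and is fully covered
itself (P2), giving SS = 1/3. One exon pair overlaps half-by-half
(E = 0.25); the second pseudogene exon raises the unique-exon total to
TE = 2, so EE = 0.125. The output GTF devotes one line to the surviving
pseudogene, keeps only the lncRNA-matched exon (`retained_exons`), and
appends each partner as `(partnerID:SS:orientation:EE)`.

The enrichment statistic on the reference piRNA-support counts (367 of 1167
transcribed loci vs 109 of 313 bidirectional loci):

```python
r = two_proportion_ztest(367, 1167, 109, 313, "less", z_decimals=2)
print(f"z={r.z:.4f} p={r.p_one_tailed:.5f}")      # z=-1.1355 p=0.12714
print(proportion_percent(367, 1167),              # 31.45
      proportion_percent(109, 313))               # 34.82
```

— no significant piRNA enrichment in the bidirectional subset.

## Command line

```sh
pseudolap fixture   --seed 7 --loci 12 --out fx/          # synthetic planted inputs
pseudolap intersect --focal fx/pseudogenes.gtf --partner fx/lncrnas.gtf \
                    --mode exon --out hits.gtf
pseudolap chain     --anchored hits.gtf --cdna fx/cdnas.gtf --est fx/ests.gtf \
                    --out tiers/
pseudolap summarize-run --pseudogenes fx/pseudogenes.gtf --lncrnas fx/lncrnas.gtf \
                    --cdna fx/cdnas.gtf --est fx/ests.gtf --out summary/
pseudolap collapse  --in a.gtf --in b.gtf --in c.gtf --out nonredundant.gtf \
                    --report venn.tsv
pseudolap overlay   --loci hits.gtf --pirna fx/pirnas.bed --snps fx/snps.tsv \
                    --window 10000 --out overlays/
pseudolap ztest     --x1 367 --n1 1167 --x2 109 --n2 313 --direction less
```

Counts per stage are logged to stderr. See `docs/methods.md` for the model,
the output dialect, and the design decisions.

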