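# tags-pgt

Combined preimplantation genetic testing for chromosomal imbalances (PGT-A)
and a monogenic disease (PGT-M) from **one mixed sequencing library**.

Some IVF assays amplify an embryo biopsy so that a single SE50 sequencing run
yields two read populations at once: ~90–96% off-target reads covering the
whole genome at ~0.1–0.65× (enough for copy-number analysis), and ~4–7%
on-target amplicon reads covering a disease gene and flanking SNPs at
10³–10⁴× (enough for direct genotyping and linkage analysis). `tags-pgt`
implements the downstream analysis of such libraries for the β-thalassemia
(*HBB*) use case: it routes aligned reads into the two fractions, calls
aneuploidies and CNVs from the low-pass fraction, diagnoses the monogenic
disease from the deep fraction by two independent routes, and merges both
into per-embryo transferability reports. A self-contained simulator
generates realistic inputs (MDA amplification artifacts included) so the
whole pipeline is testable without sequencing data.

## Method core

**Chromosomal arm.** The genome is tiled into sliding mappability windows of
100,000 uniquely-mappable 50-mer start positions with a 20,000-position
overlap (step 80,000). Per-window read counts are GC-corrected by median
scaling against an interpolated median-count-vs-GC curve, then normalized to
the genome-wide mean: the *normalized depth ratio* NDRᵢ = cᵢ / c̄ (mean NDR
is exactly 1). Ten consecutive windows are averaged into one *copy-ratio*
bin (~0.8 Mb). Recursive binary segmentation splits each chromosome at the
boundary maximizing the two-sample t statistic (Bonferroni-gated, ≥3 bins
per side), and segments are classified loss/gain/neutral against a
noise-adaptive threshold 1 ± max(0.3, 3·σ̂/√n) with σ̂ = 1.4826·MAD of the
bins. Whole chromosomes are called from the length-weighted mean NDR with
the normal range 0.7–1.3 (below → monosomy, above → trisomy); CNVs larger
than 4 Mb are reported.

**Monogenic arm.** At each panel site the *minor allele ratio*
MAR = (second-deepest allele) / (total depth) decides zygosity: sites under
100× are discarded; MAR < 5% (clinical; 10% in the validation workflow) is
homozygous, otherwise heterozygous. Disease status follows pathogenic-allele
dosage at the 11 *HBB* hotspot loci. Independently, linkage analysis phases
the trio at *informative SNPs* (heterozygous in ≥1 parent, homozygous in the
proband): because the proband is homozygous affected, the allele transmitted
to the proband tags the mutation-linked haplotype (M1/F1). Embryo
inheritance is read per SNP, runs ≥3 SNPs form haplotype blocks, block
switches are recombination events, and the block containing *HBB* decides
mutation inheritance. Concordance between the two routes, cohort statistics
with exact (Clopper–Pearson) binomial CIs, and transferability
(disease-free and chromosomally normal) complete the report.

## Worked example

Simulate an 8-embryo family in which embryo 1 carries a monosomy 13, and
run the full pipeline:

```python
from tags_pgt import SimConfig, run_pipeline

cfg = SimConfig(seed=3, n_embryos=8, genome_scale=0.1,
                embryo_aneuploidies={0: [("chr13", 1)]})
result = run_pipeline(cfg)
for r in result.embryo_reports:
    aneu = [c for c, v in r.chromosome_calls.items()
            if v not in ("disomy", "expected")]
    print(r.embryo_id, r.direct_status, r.linkage_status,
          aneu, "transferable" if r.transferable else "not transferable")
print("linkage vs direct concordance:", result.linkage_concordance.fraction)
```

prints

```
F1_E1 affected_compound_het affected_compound_het ['chr13'] not transferable
F1_E2 carrier carrier [] transferable
F1_E3 unaffected unaffected [] transferable
F1_E4 unaffected unaffected [] transferable
F1_E5 carrier carrier [] transferable
F1_E6 unaffected unaffected [] transferable
F1_E7 carrier carrier [] transferable
F1_E8 carrier carrier [] transferable
linkage vs direct concordance: 1.0
```

Embryo 1 inherited both parental pathogenic alleles (compound heterozygote)
*and* carries the planted monosomy 13; direct genotyping and trio linkage
agree for all 8 embryos, and only disease-free, chromosomally normal embryos
are flagged transferable.

The same stages are available from the shell:

```bash
tags-pgt simulate --seed 3 --out-dir sim/ --with-alignments
tags-pgt route    --alignments sim/alignments.tsv --out-prefix routed
tags-pgt cnv      --counts sim/window_counts.tsv --out-prefix cnv
tags-pgt genotype --depths sim/depths.tsv --vcf-out calls.vcf
tags-pgt linkage  --manifest sim/manifest.tsv --depths sim/depths.tsv \
                  --permissive --out linkage.json
tags-pgt run      --seed 3 --out-dir report/
```

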