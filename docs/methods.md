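# Methods

## Problem setting

A mixed-amplification IVF assay produces, per sample, one SE50 read stream
containing a low-pass genome-wide fraction (~0.1–0.65×) and a deep amplicon
fraction (10³–10⁴× over a disease-gene panel). The package consumes aligned
records (SAM/BAM or an equivalent TSV) plus a target panel and a family
manifest, and produces per-embryo chromosomal calls, monogenic diagnoses by
two routes, and transferability reports. Alignment, trimming and primer
design are upstream of this package; mosaicism, translocations and
inversions are out of scope.

## Coordinates and formats

Internal coordinates are 0-based half-open; SAM and VCF are converted at the
I/O boundary (pysam handles both). BED is consumed as 0-based half-open,
site tables as 1-based positions. Hotspot indel alleles are VCF-style
left-anchored ref/alt strings (e.g. the 4-bp deletion "CD41-42(-CTTT)" is
ref `TCTTT` → alt `T`), since the clinical names encode only the event.

The shipped β-thalassemia panel (HBB region, 65 flanking SNPs with
MAF > 0.35 within ±1 Mb, 11 hotspot loci) is a **reconstructed stand-in**:
the assay's primer/SNP supplementary tables are not distributed, so the SNP
rs-IDs and coordinates are synthetic and the hotspot coordinates follow
published HBB cDNA-to-genome conventions. Every analysis is
coordinate-generic; nothing depends on the exact stand-in positions.

## Read routing

Records are filtered to unique, non-duplicate alignments with template
≤ 500 nt (inert for SE50 data, where template = aligned span; kept for
PE-derived inputs). A read is on-target when it overlaps the amplicon
footprint — the gene region tiled into 20 amplicons plus one ~151 bp
amplicon per SNP — by ≥1 bp; `targets="sites"` restricts to the bare loci
and `flank_bp` widens the halo (the assay description does not fix a halo
width, so it is configurable with default 0). The 85-amplicon tiling is
itself a reconstruction, used for QC (per-amplicon counts, on-target rate,
uniformity = fraction of amplicons within tenfold of the mean).

## Chromosomal arm (PGT-A)

* **Windows.** Fixed *mappable-position* windows: 100,000 uniquely-mappable
  50-mer start positions per window, 20,000 overlapping between neighbours
  (step 80,000). For synthetic genomes every position is mappable, so a
  window spans ~100 kb; an explicit mappability mask is accepted for real
  genomes. Windows never span chromosomes; a chromosome smaller than one
  window becomes a single flagged window; a trailing group short of a full
  window is dropped.
* **Counting.** A read is assigned to every window containing its start
  position, so overlapping windows double-count boundary reads by design.
* **GC correction.** Windows are bucketed into 50 GC bins; the median count
  per populated bin (≥10 windows) forms a median-vs-GC curve which is
  linearly interpolated at each window's GC; corrected = raw × (global
  median)/(expected at GC). Interpolation rather than constant-per-bin
  scaling removes the within-bin residual trend; with one populated bin it
  degenerates to global median scaling.
* **NDR and copy ratio.** NDRᵢ = correctedᵢ / mean(corrected); mean NDR is
  exactly 1 by construction. Copy-ratio bins average 10 consecutive windows
  per chromosome (trailing partial bins dropped and counted). Binning
  consecutive overlapping windows keeps the bin grid at ~0.8 Mb; an optional
  `decimate=True` first keeps every ⌈window/step⌉-th window for strictly
  disjoint bins. The copy-ratio CV excludes values outside
  [Q1−1.5·IQR, Q3+1.5·IQR] before computing sd/mean.
* **Segmentation.** Recursive binary segmentation per chromosome: the split
  maximizing the pooled two-sample t statistic is accepted while
  p < 0.01/(number of candidate splits) and both sides keep ≥3 bins.
  Exactly piecewise-constant data (every maximal constant run ≥3 bins) is
  decomposed directly at its run boundaries — a zero-residual split is
  infinitely significant, and this keeps the segmenter equal to an
  exhaustive least-squares changepoint search on noiseless profiles.
  Accepted breakpoints, quantized to the ~0.8 Mb bin grid, are then
  sharpened to window resolution: the window-level NDR within ten windows
  of each boundary is re-split at the position minimizing the two-mean
  residual sum of squares, which brings boundary error down from one bin
  to a few windows.
* **Classification.** Per-sample noise σ̂ = 1.4826·MAD of the copy-ratio
  bins; a segment of n bins is loss/gain when its mean is beyond
  1 ∓ max(0.3, 3·σ̂/√n). The 0.3 floor corresponds to the smallest
  constitutive single-copy change detectable without calling sub-mosaic
  shifts (mosaicism is explicitly not called). Adjacent same-direction
  segments merge; CNVs > 4 Mb are reported, with coordinate-based digital
  karyotype lines (`del(chr2:174.6-194.0 Mb), 19.4 Mb`) — cytoband names
  would need a band track that is not shipped.
* **Chromosome calls.** Length-weighted mean NDR per chromosome against the
  0.7–1.3 normal range (autosomes: monosomy/disomy/trisomy; near zero →
  "other"). The range is applied to chromosomes, not segments. Sex is
  inferred from chrY coverage; sex chromosomes are judged against the copy
  number expected for the inferred sex and labelled "expected" when
  concordant.

## Monogenic arm (PGT-M)

* **Direct genotyping.** Per-site allele depths (four bases + indel allele
  strings as their own keys); MAR = second-deepest/total. Depth < 100× →
  no call; MAR below threshold → homozygous for the major allele; else
  heterozygous for the top two. Two thresholds ship because two workflows
  exist: 5% (clinical homozygosity rule, the default) and 10% (cell-line
  validation cutoff). Third alleles count toward the total but never toward
  the genotype. Disease classes follow pathogenic-allele dosage at the 11
  hotspots: 0 → unaffected, 1 het → carrier, hom-alt → affected homozygote,
  2 het loci → affected compound heterozygote; a no-call at a known
  parental pathogenic locus leaves the embryo undetermined rather than
  guessed. Allele dropout is flagged when an obligate allele (parents
  homozygous for different alleles) is effectively absent (<2% of reads) or
  the site failed to amplify in the embryo only.
* **Linkage.** Informative SNPs are heterozygous in ≥1 parent and
  homozygous in the proband; a SNP informs only its heterozygous parent(s).
  The study design guarantees a homozygous affected proband, which anchors
  phase: the transmitted allele defines the mutation-linked haplotype
  (M1/F1) on each side; families with other proband genotypes are out of
  scope. Embryo assignment per SNP requires that exactly one parental
  haplotype is compatible given the other parent's genotype (doubly
  ambiguous sites are skipped). Runs of ≥3 consistent assignments form
  blocks (min_block = 3 separates recombination from genotyping noise —
  the assay description is silent here); breakpoints separate adjacent
  blocks with different labels, and the block containing (or nearest) the
  gene decides mutation inheritance, which handles a crossover between the
  panel and the gene. The clinical rule demands ≥10 informative SNPs per
  side; because reported cohorts average ~8 per embryo, a documented
  permissive mode at 5 ships as well (`min_informative`). Concordance
  between linkage and direct statuses treats the two affected classes as
  equivalent (linkage alone cannot separate them) and excludes embryos
  undetermined on either side.

## Reporting

Percentages round half-up to one decimal (29/54 → 53.7). Transferable =
disease-free (carriers included by default, configurable) AND no
aneuploidy AND no reported CNV; both the disease-only and combined rates
are returned. Chromosomal classes partition the cohort with aneuploidy
taking precedence over CNV. Confidence intervals are exact
Clopper–Pearson beta-quantile intervals (full success: lower bound
(α/2)^(1/n), upper exactly 1). External concordance excludes externally
undetermined embryos from the denominator and lists discordant rows without
adjudicating which side is right.

## Simulator

The generator emulates the assay's operating ranges, which are its default
parameters: 0.3× genome-wide depth, 10,000× mean site depth (log-normal,
σ_log = 0.5), 1% flat base-error rate, ADO rate 2/5070 ≈ 4×10⁻⁴ per het
site, and an on-target read share that emerges at ~4–7% of a ~20 M-read
library (85 amplicons × ~10⁴ reads, each read covering its amplicon's
central site). Distribution shapes are modelling choices: beta-binomial
allele fractions (ρ = 0.05) for MDA preferential amplification,
negative-binomial window counts (variance μ + 0.05 μ²) for low-pass
sampling plus amplification noise, Beta(0.41·150, 0.59·150) per-window GC
with an optional polynomial GC-bias factor, Poisson(0.01) crossovers per
meiosis uniform over the panel span. Parents are heterozygous at their
assigned hotspots (CD41-42 paternal, CD17 maternal by default — loci from
the clinical cohorts); the proband inherits both mutation-linked
haplotypes. Whole runs are byte-deterministic given the seed.

What the simulator does **not** capture: read-level base sequences and
quality profiles, alignment and mapping artifacts (mappability is uniform
on synthetic genomes), correlated noise between overlapping windows (counts
are drawn independently per window), locus-specific amplification bias
beyond the symmetric beta-binomial, chromosome-specific GC structure, and
mosaicism. Passing tests therefore demonstrate the correctness and
statistical behaviour of the analysis chain under the stated noise model,
not performance on real sequencing data.

## Problem sizes used in checks

The deletion-recovery and euploid-specificity checks simulate window
*counts* directly on the full-size female genome (≈38,000 windows,
≈3,800 copy-ratio bins), which keeps a complete chain run under ~2 s;
read-level simulations (routing, library composition) use miniature genomes
(1–2% of full length) or fixed read totals, since only fractions are under
test. Genotyping-recovery checks use synthetic panels of 2,000–10,000 SNPs;
linkage consistency uses 200 simulated embryos across 10 families, and
noise tolerance 1,000 embryos.

## Known limitations

* Chromosome-level NDR calls assume most of the genome is diploid (the
  normalization mean shifts under multiple large aneuploidies).
* The binary-segmentation gate is a pooled-t approximation, not a
  permutation test; very short low-amplitude events near the 0.3 floor are
  conservatively left neutral.
* The panel fixture is a stand-in; clinical use requires the real primer
  and SNP coordinates.
* Linkage requires a homozygous affected proband; no population phasing or
  imputation is attempted.
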