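"""Domain types shared by every stage of the PGT-A/M pipeline.

Coordinates are 0-based half-open throughout; SAM/VCF readers and writers
convert at the boundary.  Alignment *tables* (the bulk representation used by
the router and counter) are pandas DataFrames with the columns of
:data:`ALIGNMENT_COLUMNS`; :class:`AlignmentRecord` is the per-record view
used at the SAM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .genome import VALID_CHROMS

ALIGNMENT_COLUMNS = (
    "read_id", "chrom", "start", "aligned_len",
    "is_unique", "is_duplicate", "template_len",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.chrom not in VALID_CHROMS:
            raise ValueError(f"unknown chromosome {self.chrom!r} (hg19 naming)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def padded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - flank),
                               self.end + flank)


@dataclass(frozen=True)
class AlignmentRecord:
    """A single aligned read (single-end, or one PE-derived record)."""

    read_id: str
    interval: GenomicInterval
    aligned_len: int
    is_unique: bool
    is_duplicate: bool
    template_len: int = 0

    def __post_init__(self) -> None:
        if self.aligned_len <= 0:
            raise ValueError("aligned_len must be positive")
        if self.interval.length != self.aligned_len:
            raise ValueError("interval length must equal aligned_len")
        if self.template_len == 0:
            # SE reads: template equals the aligned span
            object.__setattr__(self, "template_len", self.aligned_len)


def alignments_to_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Convert AlignmentRecords to the bulk alignment-table representation."""
    rows = [(r.read_id, r.interval.chrom, r.interval.start, r.aligned_len,
             r.is_unique, r.is_duplicate, r.template_len) for r in records]
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def frame_to_alignments(frame: pd.DataFrame) -> list[AlignmentRecord]:
    return [
        AlignmentRecord(
            read_id=str(row.read_id),
            interval=GenomicInterval(row.chrom, int(row.start),
                                     int(row.start) + int(row.aligned_len)),
            aligned_len=int(row.aligned_len),
            is_unique=bool(row.is_unique),
            is_duplicate=bool(row.is_duplicate),
            template_len=int(row.template_len),
        )
        for row in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP on the linkage panel."""

    id: str
    locus: GenomicInterval
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.locus.length != 1:
            raise ValueError(f"SNP {self.id}: locus must have length 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles identical")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"SNP {self.id}: MAF {self.maf} outside (0, 0.5]")

    @property
    def position(self) -> int:
        return self.locus.start


@dataclass(frozen=True)
class HotspotLocus:
    """A named pathogenic hotspot (substitution or small indel).

    Alleles are VCF-style left-anchored ref/alt strings, so e.g. the
    4-bp deletion "CD41-42 (-CTTT)" is encoded as ref="TCTTT", alt="T".
    """

    name: str
    locus: GenomicInterval
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"hotspot {self.name}: empty allele string")

    @property
    def position(self) -> int:
        return self.locus.start


@dataclass
class TargetPanel:
    """The amplicon panel: gene regions plus flanking SNPs and hotspots."""

    gene_regions: list[GenomicInterval]
    snp_sites: list[SnpSite]
    hotspot_loci: list[HotspotLocus]
    n_gene_amplicons: int = 20

    def __post_init__(self) -> None:
        if not self.snp_sites:
            raise ValueError("panel must contain at least one SNP site")
        names = [h.name for h in self.hotspot_loci]
        if len(set(names)) != len(names):
            raise ValueError("hotspot names must be unique")
        self.snp_sites = sorted(
            self.snp_sites, key=lambda s: (s.locus.chrom, s.position))

    @property
    def all_sites(self) -> list[SnpSite | HotspotLocus]:
        return list(self.snp_sites) + list(self.hotspot_loci)

    def target_intervals(self) -> list[GenomicInterval]:
        return (list(self.gene_regions)
                + [s.locus for s in self.snp_sites]
                + [h.locus for h in self.hotspot_loci])

    def hotspot(self, name: str) -> HotspotLocus:
        for h in self.hotspot_loci:
            if h.name == name:
                return h
        raise KeyError(name)

    def amplicons(self) -> list[tuple[str, GenomicInterval]]:
        """Named amplicon intervals: the gene regions tiled into
        ``n_gene_amplicons`` pieces plus one amplicon per SNP site.

        The real assay used 85 primer pairs (gene region + 65 SNPs); the
        per-amplicon tiling here is a reconstruction, since the primer
        coordinates themselves are not part of this package.
        """
        out: list[tuple[str, GenomicInterval]] = []
        total = sum(r.length for r in self.gene_regions)
        made = 0
        for ri, region in enumerate(self.gene_regions):
            n_here = (self.n_gene_amplicons - made if ri == len(self.gene_regions) - 1
                      else max(1, round(self.n_gene_amplicons * region.length / total)))
            n_here = max(1, n_here)
            edges = [region.start + (region.length * k) // n_here
                     for k in range(n_here + 1)]
            for k in range(n_here):
                if edges[k] < edges[k + 1]:
                    out.append((f"gene_{ri}_{k}",
                                GenomicInterval(region.chrom, edges[k], edges[k + 1])))
                    made += 1
        half = 75  # nominal amplicon half-width around each SNP
        for s in self.snp_sites:
            out.append((s.id, GenomicInterval(
                s.locus.chrom, max(0, s.position - half), s.position + half + 1)))
        return out


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    role: str  # father | mother | proband | embryo


@dataclass
class SampleManifest:
    """One family: a trio plus any number of embryos, with the parents'
    known pathogenic hotspot alleles."""

    family_id: str
    members: list[SampleInfo]
    parental_hotspots: dict[str, str] = field(default_factory=dict)
    # role ("father"/"mother") → hotspot name

    def __post_init__(self) -> None:
        for role in ("father", "mother", "proband"):
            if sum(m.role == role for m in self.members) != 1:
                raise ValueError(
                    f"family {self.family_id}: need exactly one {role}")

    def member(self, role: str) -> SampleInfo:
        return next(m for m in self.members if m.role == role)

    @property
    def embryos(self) -> list[SampleInfo]:
        return [m for m in self.members if m.role == "embryo"]


# ---------------------------------------------------------------------------
# PGT-M types
# ---------------------------------------------------------------------------

@dataclass
class SiteAlleleDepth:
    """Per-site read depth by allele; basis of the minor-allele-ratio call."""

    site_id: str
    depth_by_allele: dict[str, int]
    chrom: str | None = None
    position: int | None = None

    @property
    def total_depth(self) -> int:
        return sum(self.depth_by_allele.values())

    @property
    def mar(self) -> float:
        """Minor allele ratio: second-highest allele depth / total depth."""
        total = self.total_depth
        if total == 0:
            return 0.0
        depths = sorted(self.depth_by_allele.values(), reverse=True)
        return (depths[1] / total) if len(depths) > 1 else 0.0

    def top_alleles(self, n: int = 2) -> list[str]:
        ranked = sorted(self.depth_by_allele.items(),
                        key=lambda kv: (-kv[1], kv[0]))
        return [a for a, _ in ranked[:n]]


@dataclass
class GenotypeCall:
    site_id: str
    alleles: tuple[str, str] | None
    zygosity: str  # "hom" | "het" | "no_call"
    mar: float
    depth: int
    qc_flags: tuple[str, ...] = ()

    def has_allele(self, allele: str) -> bool:
        return self.alleles is not None and allele in self.alleles


UNAFFECTED = "unaffected"
CARRIER = "carrier"
AFFECTED_HOM = "affected_homozygous"
AFFECTED_COMPOUND = "affected_compound_het"
UNDETERMINED = "undetermined"

DISEASE_CLASSES = (UNAFFECTED, CARRIER, AFFECTED_HOM, AFFECTED_COMPOUND,
                   UNDETERMINED)

AFFECTED_CLASSES = frozenset({AFFECTED_HOM, AFFECTED_COMPOUND})


@dataclass
class DiseaseStatus:
    status: str
    supporting_calls: list[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in DISEASE_CLASSES:
            raise ValueError(f"unknown disease status {self.status!r}")

    @property
    def affected(self) -> bool:
        return self.status in AFFECTED_CLASSES


# ---------------------------------------------------------------------------
# Linkage types
# ---------------------------------------------------------------------------

@dataclass
class PhasedTrio:
    """Parental haplotypes over the informative panel SNPs.

    M1/F1 are by construction the haplotypes transmitted to the homozygous
    affected proband, i.e. the mutation-linked haplotypes.
    """

    snp_ids: list[str]          # coordinate-sorted informative SNPs
    positions: list[int]
    M1: dict[str, str]
    M2: dict[str, str]
    F1: dict[str, str]
    F2: dict[str, str]
    maternal_informative: list[str]
    paternal_informative: list[str]
    mutation_linked: dict[str, str] = field(
        default_factory=lambda: {"mother": "M1", "father": "F1"})


@dataclass
class EmbryoInheritance:
    embryo_id: str
    snp_ids: list[str]
    positions: list[int]
    maternal_assign: list[str]   # "M1" | "M2" | "-" per SNP
    paternal_assign: list[str]   # "F1" | "F2" | "-"
    maternal_blocks: list[tuple[str, int, int]]  # (label, first_idx, last_idx)
    paternal_blocks: list[tuple[str, int, int]]
    n_informative_used: dict[str, int]
    maternal_mutation_inherited: bool | None
    paternal_mutation_inherited: bool | None
    inferred_disease_status: str
    recombination_breakpoints: list[tuple[str, int, int]]
    # (parent, left bp position, right bp position)
    noise_flags: int = 0


# ---------------------------------------------------------------------------
# Reporting types
# ---------------------------------------------------------------------------

@dataclass
class EmbryoReport:
    embryo_id: str
    direct_status: str
    linkage_status: str
    chromosome_calls: dict[str, str] = field(default_factory=dict)
    cnv_calls: list = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    allow_carrier: bool = True

    @property
    def has_aneuploidy(self) -> bool:
        return any(c not in ("disomy", "expected")
                   for c in self.chromosome_calls.values())

    @property
    def disease_free(self) -> bool:
        ok = {UNAFFECTED, CARRIER} if self.allow_carrier else {UNAFFECTED}
        return self.direct_status in ok

    @property
    def transferable(self) -> bool:
        return (self.disease_free and not self.has_aneuploidy
                and not self.cnv_calls)


@dataclass
class CohortSummary:
    n_embryos: int
    disease_counts: dict[str, int]
    disease_percent: dict[str, float]
    chromosomal_counts: dict[str, int]
    chromosomal_percent: dict[str, float]
    transferable_rate_disease_only: float
    transferable_rate_combined: float
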