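"""Synthetic-data generator emulating a mixed low-pass + deep-amplicon
library so every pipeline stage is testable without sequencing data.

What it emulates: trio families segregating pathogenic hotspot alleles
(Mendelian transmission with optional recombination), MDA amplification
artifacts at deep amplicon sites (allele dropout, beta-binomially
overdispersed allele fractions from preferential amplification, a flat 1%
base-error rate, log-normal site depths around 10,000×), negative-binomial
low-pass window counts at 0.3× with optional GC bias and planted
aneuploidies/CNVs, and the mixed on/off-target read stream itself.

Defaults follow the reported operating ranges of the assay (0.3× genome
depth, ~10⁴× target depth, ADO ≈ 2/5070 sites).  Distribution *shapes*
(beta-binomial, log-normal, negative binomial) are modelling choices; the
methods note discusses what they do and do not capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import genome_length, scaled_genome
from .models import (
    AFFECTED_COMPOUND,
    AFFECTED_HOM,
    CARRIER,
    UNAFFECTED,
    GenomicInterval,
    SampleInfo,
    SampleManifest,
    SiteAlleleDepth,
    TargetPanel,
)
from .cnv import WindowProfile

BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    seed: int = 0
    n_embryos: int = 8
    snp_maf: float = 0.4                 # fallback when a site has no MAF
    father_hotspot: str = "CD41-42(-CTTT)"
    mother_hotspot: str = "CD17(A>T)"
    recombination_rate: float = 0.01     # crossovers per meiosis per panel
    ado_rate: float = 0.0004             # ≈ 2 dropouts per 5070 het sites
    pref_amp_rho: float = 0.05           # beta-binomial overdispersion
    mean_site_depth: float = 10_000.0
    depth_log_sigma: float = 0.5
    error_rate: float = 0.01
    wgs_mean_depth: float = 0.3
    read_len: int = 50
    gc_mean: float = 0.41
    gc_concentration: float = 150.0
    gc_bias_coefficients: tuple[float, ...] = (1.0,)  # polynomial in GC
    nb_dispersion: float = 0.05          # var = μ + α μ²
    cnv_events: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    aneuploidies: list[tuple[str, int]] = field(default_factory=list)
    # per-embryo karyotype events, keyed by 0-based embryo index
    embryo_cnv_events: dict[int, list] = field(default_factory=dict)
    embryo_aneuploidies: dict[int, list] = field(default_factory=dict)
    sex: str = "female"
    genome_scale: float = 0.1            # miniature genome for read-level sims
    dup_rate: float = 0.01
    nonunique_rate: float = 0.01

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def validate(self) -> None:
        for name in ("recombination_rate", "ado_rate", "pref_amp_rho",
                     "error_rate", "dup_rate", "nonunique_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_site_depth <= 0 or self.wgs_mean_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass
class MeiosisTruth:
    hap_choice: np.ndarray        # 0/1 parental haplotype index per locus
    crossovers: list[int]         # crossover positions (bp)


@dataclass
class SampleTruth:
    sample_id: str
    genotypes: dict[str, tuple[str, str]]   # site_id → (allele_1, allele_2)


@dataclass
class EmbryoTruth(SampleTruth):
    maternal: MeiosisTruth = None
    paternal: MeiosisTruth = None
    maternal_mutation: bool = False
    paternal_mutation: bool = False
    disease_status: str = UNAFFECTED


@dataclass
class FamilyTruth:
    manifest: SampleManifest
    panel: TargetPanel
    site_ids: list[str]
    positions: np.ndarray
    father_haps: tuple[dict[str, str], dict[str, str]]
    mother_haps: tuple[dict[str, str], dict[str, str]]
    father_mut_hap: int
    mother_mut_hap: int
    father: SampleTruth = None
    mother: SampleTruth = None
    proband: SampleTruth = None
    embryos: list[EmbryoTruth] = field(default_factory=list)

    def sample_truths(self) -> dict[str, SampleTruth]:
        out = {self.father.sample_id: self.father,
               self.mother.sample_id: self.mother,
               self.proband.sample_id: self.proband}
        for e in self.embryos:
            out[e.sample_id] = e
        return out


def _transmit(haps: tuple[dict[str, str], dict[str, str]], site_ids, positions,
              rate: float, rng: np.random.Generator) -> tuple[MeiosisTruth, dict[str, str]]:
    """One meiosis: Poisson(rate) crossovers at uniform panel positions."""
    n_cross = rng.poisson(rate)
    lo, hi = int(positions.min()), int(positions.max())
    crossovers = sorted(int(p) for p in rng.integers(lo, hi + 1, size=n_cross))
    start = int(rng.integers(0, 2))
    parity = np.searchsorted(crossovers, positions, side="right") if crossovers \
        else np.zeros(len(positions), dtype=int)
    choice = (start + parity) % 2
    transmitted = {sid: haps[c][sid] for sid, c in zip(site_ids, choice)}
    return MeiosisTruth(choice, crossovers), transmitted


def simulate_family(config: SimConfig, panel: TargetPanel,
                    rng: np.random.Generator | None = None,
                    family_id: str = "F1") -> FamilyTruth:
    """Draw a trio family plus embryos by Mendelian transmission.

    Parents are heterozygous at their assigned hotspot with the mutation
    placed on one haplotype; the proband inherits both mutation-linked
    haplotypes (homozygous affected, the study's phase anchor).  Embryo
    meioses draw Poisson(recombination_rate) crossovers at uniform panel
    positions.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    site_ids = [s.id for s in panel.snp_sites] + [h.name for h in panel.hotspot_loci]
    positions = np.array([s.position for s in panel.snp_sites]
                         + [h.position for h in panel.hotspot_loci])
    order = np.argsort(positions, kind="stable")
    site_ids = [site_ids[i] for i in order]
    positions = positions[order]

    def parent_haps(hotspot_name: str) -> tuple[tuple[dict, dict], int]:
        h0, h1 = {}, {}
        for s in panel.snp_sites:
            maf = s.maf or config.snp_maf
            for h in (h0, h1):
                h[s.id] = s.alt_allele if rng.random() < maf else s.ref_allele
        mut_hap = int(rng.integers(0, 2))
        for h in panel.hotspot_loci:
            h0[h.name] = h1[h.name] = h.ref_allele
        target = panel.hotspot(hotspot_name)
        (h0, h1)[mut_hap][target.name] = target.alt_allele
        return (h0, h1), mut_hap

    father_haps, f_mut = parent_haps(config.father_hotspot)
    mother_haps, m_mut = parent_haps(config.mother_hotspot)

    def gt_from(h_a: dict, h_b: dict) -> dict[str, tuple[str, str]]:
        return {sid: (h_a[sid], h_b[sid]) for sid in site_ids}

    father = SampleTruth(f"{family_id}_father", gt_from(*father_haps))
    mother = SampleTruth(f"{family_id}_mother", gt_from(*mother_haps))
    # proband: homozygous affected ⇒ inherits both mutation-linked haplotypes
    proband = SampleTruth(
        f"{family_id}_proband",
        {sid: (mother_haps[m_mut][sid], father_haps[f_mut][sid])
         for sid in site_ids})

    embryos = []
    for k in range(config.n_embryos):
        m_mei, m_alleles = _transmit(mother_haps, site_ids, positions,
                                     config.recombination_rate, rng)
        f_mei, f_alleles = _transmit(father_haps, site_ids, positions,
                                     config.recombination_rate, rng)
        gts = {sid: (m_alleles[sid], f_alleles[sid]) for sid in site_ids}
        m_hot = panel.hotspot(config.mother_hotspot)
        f_hot = panel.hotspot(config.father_hotspot)
        m_inherit = m_alleles[m_hot.name] == m_hot.alt_allele
        f_inherit = f_alleles[f_hot.name] == f_hot.alt_allele
        if m_inherit and f_inherit:
            status = (AFFECTED_HOM if config.mother_hotspot == config.father_hotspot
                      else AFFECTED_COMPOUND)
        elif m_inherit or f_inherit:
            status = CARRIER
        else:
            status = UNAFFECTED
        embryos.append(EmbryoTruth(
            f"{family_id}_E{k + 1}", gts, m_mei, f_mei, m_inherit, f_inherit,
            status))

    members = ([SampleInfo(father.sample_id, "father"),
                SampleInfo(mother.sample_id, "mother"),
                SampleInfo(proband.sample_id, "proband")]
               + [SampleInfo(e.sample_id, "embryo") for e in embryos])
    manifest = SampleManifest(family_id, members,
                              {"father": config.father_hotspot,
                               "mother": config.mother_hotspot})
    return FamilyTruth(manifest, panel, site_ids, positions,
                       father_haps, mother_haps, f_mut, m_mut,
                       father, mother, proband, embryos)


# ---------------------------------------------------------------------------
# Allele depths (MDA artifacts)
# ---------------------------------------------------------------------------

def _error_allele(site_alleles: tuple[str, str]) -> str:
    for b in BASES:
        if b not in site_alleles:
            return b
    return "N"


def simulate_allele_depths(truth: FamilyTruth, config: SimConfig,
                           rng: np.random.Generator | None = None,
                           ado_log: list | None = None
                           ) -> dict[str, list[SiteAlleleDepth]]:
    """Per-sample per-site allele depth tables with MDA distortions.

    Heterozygous sites drop one allele with probability ``ado_rate``;
    otherwise the allele fraction is beta-binomial around ½ with
    overdispersion ``pref_amp_rho``.  Total depth is log-normal around
    ``mean_site_depth``; a flat ``error_rate`` of reads lands on a third
    allele.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    by_site = {(s.id if hasattr(s, "id") else s.name): s
               for s in truth.panel.all_sites}
    rho = config.pref_amp_rho
    beta_a = (1.0 - rho) / (2.0 * rho) if rho > 0 else None
    mu_log = np.log(config.mean_site_depth) - config.depth_log_sigma ** 2 / 2

    out: dict[str, list[SiteAlleleDepth]] = {}
    for sample_id, struth in truth.sample_truths().items():
        sads = []
        for sid in truth.site_ids:
            a1, a2 = struth.genotypes[sid]
            site = by_site[sid]
            depth = int(np.round(np.exp(rng.normal(mu_log, config.depth_log_sigma))))
            depths: dict[str, int] = {}
            if a1 != a2:  # heterozygous
                if rng.random() < config.ado_rate:
                    kept = a1 if rng.random() < 0.5 else a2
                    depths[kept] = depth
                    if ado_log is not None:
                        ado_log.append((sample_id, sid))
                else:
                    f = rng.beta(beta_a, beta_a) if beta_a is not None else 0.5
                    n1 = int(rng.binomial(depth, f))
                    depths[a1] = n1
                    depths[a2] = depth - n1
            else:
                depths[a1] = depth
            n_err = int(rng.binomial(depth, config.error_rate))
            if n_err:
                # errors taken proportionally from the true alleles
                true_alleles = list(depths)
                weights = np.array([depths[a] for a in true_alleles], dtype=float)
                take = rng.multinomial(n_err, weights / weights.sum())
                err = _error_allele((site.ref_allele, site.alt_allele))
                for a, t in zip(true_alleles, take):
                    depths[a] -= int(t)
                depths[err] = depths.get(err, 0) + n_err
            sads.append(SiteAlleleDepth(sid, depths, site.locus.chrom,
                                        site.position))
        out[sample_id] = sads
    return out


# ---------------------------------------------------------------------------
# Window counts (low-pass arm)
# ---------------------------------------------------------------------------

def window_copy_numbers(profile: WindowProfile, config: SimConfig,
                        cnv_events=None, aneuploidies=None) -> np.ndarray:
    """True copy number per window from the configured events (baseline 2;
    female chrY = 0, male sex chromosomes = 1)."""
    cnv_events = config.cnv_events if cnv_events is None else cnv_events
    aneuploidies = config.aneuploidies if aneuploidies is None else aneuploidies
    df = profile.df
    copies = np.full(len(df), 2.0)
    if config.sex == "female":
        copies[df["chrom"] == "chrY"] = 0.0
    else:
        copies[df["chrom"].isin(["chrX", "chrY"])] = 1.0
    for chrom, copy in aneuploidies:
        copies[(df["chrom"] == chrom).to_numpy()] = copy
    mid = ((df["start"] + df["end"]) // 2).to_numpy()
    for iv, copy in cnv_events:
        sel = ((df["chrom"] == iv.chrom).to_numpy()
               & (mid >= iv.start) & (mid < iv.end))
        copies[sel] = copy
    return copies


def simulate_window_counts(profile: WindowProfile, config: SimConfig,
                           rng: np.random.Generator | None = None,
                           cnv_events=None, aneuploidies=None) -> WindowProfile:
    """Negative-binomial window counts: mean = base × copy/2 × GC bias,
    variance = μ + α μ²; GC fractions drawn per window and stored."""
    config.validate()
    rng = config.rng() if rng is None else rng
    df = profile.df.copy()
    k = config.gc_concentration
    gc = rng.beta(config.gc_mean * k, (1 - config.gc_mean) * k, size=len(df))
    df["gc"] = gc
    copies = window_copy_numbers(profile.with_df(df), config,
                                 cnv_events, aneuploidies)
    base = (config.wgs_mean_depth * df["n_mappable"].to_numpy(dtype=float)
            / config.read_len)
    bias = np.polyval(list(config.gc_bias_coefficients)[::-1], gc)
    bias = np.clip(bias, 1e-6, None)
    bias = bias / bias.mean()
    mu = base * copies / 2.0 * bias
    alpha = config.nb_dispersion
    counts = np.zeros(len(df), dtype=np.int64)
    pos = mu > 0
    if alpha > 0:
        n = 1.0 / alpha
        p = n / (n + mu[pos])
        counts[pos] = rng.negative_binomial(n, p)
    else:
        counts[pos] = rng.poisson(mu[pos])
    df["raw_count"] = counts
    return profile.with_df(df)


# ---------------------------------------------------------------------------
# Mixed read stream
# ---------------------------------------------------------------------------

def simulate_library(config: SimConfig, panel: TargetPanel,
                     rng: np.random.Generator | None = None,
                     genome_sizes: dict[str, int] | None = None,
                     n_reads: int | None = None,
                     frac_tes: float | None = None) -> pd.DataFrame:
    """Simulate the mixed alignment table of one library.

    Off-target reads fall uniformly over the genome at ``wgs_mean_depth``;
    on-target reads fall over the panel amplicons at ``mean_site_depth``.
    With ``n_reads`` and ``frac_tes`` given, those override the depth-driven
    totals (useful for calibrated routing tests).  A small fraction of reads
    is flagged duplicate or non-unique to exercise the filters.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    if genome_sizes is None:
        genome_sizes = scaled_genome(config.genome_scale,
                                     include_y=config.sex != "female")
    glen = genome_length(genome_sizes)
    read_len = config.read_len
    amplicons = panel.amplicons()

    if n_reads is not None and frac_tes is not None:
        n_on = int(rng.binomial(n_reads, frac_tes))
        n_off = n_reads - n_on
        amp_weights = np.ones(len(amplicons))
    else:
        # short amplicons: every read covers the central target site, so
        # reads per amplicon ≈ the site depth
        n_off = int(rng.poisson(config.wgs_mean_depth * glen / read_len))
        amp_weights = np.full(len(amplicons), config.mean_site_depth)
        n_on = int(rng.poisson(amp_weights.sum()))

    chroms = list(genome_sizes)
    lens = np.array([genome_sizes[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_off, p=lens / lens.sum())
    off_pos = (rng.random(n_off) * (lens[chrom_idx] - read_len)).astype(np.int64)
    off = pd.DataFrame({
        "read_id": np.char.add("off_", np.arange(n_off).astype(str)),
        "chrom": np.array(chroms, dtype=object)[chrom_idx],
        "start": off_pos,
    })

    amp_idx = rng.choice(len(amplicons), size=n_on,
                         p=amp_weights / amp_weights.sum())
    centers = np.array([(iv.start + iv.end) // 2 for _, iv in amplicons])
    starts = np.array([iv.start for _, iv in amplicons])
    amp_chroms = np.array([iv.chrom for _, iv in amplicons], dtype=object)
    # read start drawn so the read covers the amplicon's central site
    lo = np.maximum(starts, centers - read_len + 1)[amp_idx]
    hi = centers[amp_idx] + 1
    on_start = lo + (rng.random(n_on) * (hi - lo)).astype(np.int64)
    on = pd.DataFrame({
        "read_id": np.char.add("on_", np.arange(n_on).astype(str)),
        "chrom": amp_chroms[amp_idx],
        "start": on_start,
    })

    df = pd.concat([off, on], ignore_index=True)
    n = len(df)
    df["aligned_len"] = read_len
    df["is_unique"] = rng.random(n) >= config.nonunique_rate
    df["is_duplicate"] = rng.random(n) < config.dup_rate
    df["template_len"] = read_len
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))
                     ).reset_index(drop=True)
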