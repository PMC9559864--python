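"""Trio-phased haplotype linkage analysis of the target-gene region.

Phase is anchored by the homozygous affected proband: at every informative
SNP (heterozygous in at least one parent, homozygous in the proband) the
allele transmitted to the proband defines the mutation-linked haplotype
(M1 maternally, F1 paternally), because the proband inherited each parent's
pathogenic allele.  Embryo haplotype inheritance is then read off per SNP,
runs of consistent assignment form blocks, and a block switch of at least
``min_block`` SNPs is a recombination event (shorter flips are genotyping
noise).  When a recombination block spans the gene, the block containing the
gene decides mutation inheritance; otherwise the majority haplotype does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .models import (
    AFFECTED_COMPOUND,
    AFFECTED_HOM,
    CARRIER,
    UNAFFECTED,
    UNDETERMINED,
    EmbryoInheritance,
    GenotypeCall,
    PhasedTrio,
    SnpSite,
    TargetPanel,
)

MIN_INFORMATIVE = 10          # clinical default
MIN_INFORMATIVE_PERMISSIVE = 5


class MendelianInconsistencyError(ValueError):
    pass


def _genotype_set(call: GenotypeCall | None) -> frozenset[str] | None:
    if call is None or call.zygosity == "no_call" or call.alleles is None:
        return None
    return frozenset(call.alleles)


@dataclass(frozen=True)
class InformativeSnp:
    snp: SnpSite
    informs_father: bool
    informs_mother: bool


def select_informative_snps(father_gt: Mapping[str, GenotypeCall],
                            mother_gt: Mapping[str, GenotypeCall],
                            proband_gt: Mapping[str, GenotypeCall],
                            panel: TargetPanel) -> list[InformativeSnp]:
    """SNPs heterozygous in at least one parent but homozygous in the
    proband, coordinate-sorted; each tagged with the parent(s) it informs
    (a SNP informs a parent only if that parent is heterozygous)."""
    out = []
    for snp in panel.snp_sites:  # already coordinate-sorted
        f = father_gt.get(snp.id)
        m = mother_gt.get(snp.id)
        p = proband_gt.get(snp.id)
        if f is None or m is None or p is None:
            continue
        if p.zygosity != "hom":
            continue
        f_het = f.zygosity == "het"
        m_het = m.zygosity == "het"
        if f_het or m_het:
            out.append(InformativeSnp(snp, f_het, m_het))
    return out


def phase_trio(father_gt: Mapping[str, GenotypeCall],
               mother_gt: Mapping[str, GenotypeCall],
               proband_gt: Mapping[str, GenotypeCall],
               informative: Sequence[InformativeSnp],
               max_inconsistent: int = 2) -> PhasedTrio:
    """Proband-anchored phasing over the informative SNPs.

    At each informative SNP the proband's homozygous allele was transmitted
    by both parents; for a heterozygous parent it defines that parent's
    mutation-linked haplotype (M1/F1), the other allele the alternative
    haplotype (M2/F2).  A homozygous parent contributes the same allele to
    both haplotypes.  Proband alleles incompatible with a parent at more
    than ``max_inconsistent`` sites raise a Mendelian-inconsistency error.
    """
    M1, M2, F1, F2 = {}, {}, {}, {}
    snp_ids, positions = [], []
    maternal_inf, paternal_inf = [], []
    inconsistent = 0
    for info in informative:
        sid = info.snp.id
        p = _genotype_set(proband_gt[sid])
        if p is None or len(p) != 1:
            continue
        (transmitted,) = p
        f = _genotype_set(father_gt.get(sid))
        m = _genotype_set(mother_gt.get(sid))
        if f is None or m is None:
            continue
        if transmitted not in f or transmitted not in m:
            inconsistent += 1
            continue
        snp_ids.append(sid)
        positions.append(info.snp.position)
        if info.informs_mother:
            other = next(a for a in m if a != transmitted)
            M1[sid], M2[sid] = transmitted, other
            maternal_inf.append(sid)
        else:
            M1[sid] = M2[sid] = transmitted if transmitted in m else next(iter(m))
        if info.informs_father:
            other = next(a for a in f if a != transmitted)
            F1[sid], F2[sid] = transmitted, other
            paternal_inf.append(sid)
        else:
            F1[sid] = F2[sid] = transmitted if transmitted in f else next(iter(f))
    if inconsistent > max_inconsistent:
        raise MendelianInconsistencyError(
            f"proband inconsistent with parents at {inconsistent} informative SNPs")
    return PhasedTrio(snp_ids, positions, M1, M2, F1, F2,
                      maternal_inf, paternal_inf)


def _assign_parent(embryo: frozenset[str], this_parent: tuple[str, str],
                   other_parent_gt: frozenset[str]) -> str | None:
    """Which of the parent's two haplotype alleles is compatible with the
    embryo genotype given the other parent's contribution; None if ambiguous
    or inconsistent.  ``this_parent`` = (hap1 allele, hap2 allele)."""
    a1, a2 = this_parent
    if a1 == a2:
        return None  # uninformative for this parent
    compatible = []
    for hap, allele in (("1", a1), ("2", a2)):
        if allele not in embryo:
            continue
        # the embryo's other allele must be transmittable by the other parent
        rest = list(embryo - {allele}) or [allele]  # hom embryo: same allele
        if len(embryo) == 1:
            other_allele = allele
        else:
            (other_allele,) = rest
        if other_allele in other_parent_gt:
            compatible.append(hap)
    if len(compatible) == 1:
        return compatible[0]
    return None


def infer_embryo(embryo_gt: Mapping[str, GenotypeCall], phased: PhasedTrio,
                 panel: TargetPanel, embryo_id: str = "embryo",
                 min_informative: int = MIN_INFORMATIVE,
                 min_block: int = 3) -> EmbryoInheritance:
    """Per-SNP parental-haplotype assignment and disease-genotype inference.

    Sites with no_call are skipped.  A side with fewer than
    ``min_informative`` assigned SNPs leaves the genotype undetermined
    rather than guessed.
    """
    snp_ids, positions = [], []
    m_assign, p_assign = [], []
    father_gt_sets = {}
    mother_gt_sets = {}
    for sid in phased.snp_ids:
        father_gt_sets[sid] = frozenset({phased.F1[sid], phased.F2[sid]})
        mother_gt_sets[sid] = frozenset({phased.M1[sid], phased.M2[sid]})
    for sid, pos in zip(phased.snp_ids, phased.positions):
        e = _genotype_set(embryo_gt.get(sid))
        if e is None:
            continue
        snp_ids.append(sid)
        positions.append(pos)
        m = _assign_parent(e, (phased.M1[sid], phased.M2[sid]), father_gt_sets[sid])
        f = _assign_parent(e, (phased.F1[sid], phased.F2[sid]), mother_gt_sets[sid])
        m_assign.append(f"M{m}" if m else "-")
        p_assign.append(f"F{f}" if f else "-")

    gene_pos = _gene_midpoint(panel)
    m_blocks, m_bps, m_noise = _blocks(m_assign, positions, min_block)
    p_blocks, p_bps, p_noise = _blocks(p_assign, positions, min_block)
    n_used = {"mother": sum(a != "-" for a in m_assign),
              "father": sum(a != "-" for a in p_assign)}

    m_inherited = _mutation_inherited(m_blocks, positions, gene_pos, "M1")
    f_inherited = _mutation_inherited(p_blocks, positions, gene_pos, "F1")
    if n_used["mother"] < min_informative or n_used["father"] < min_informative:
        status = UNDETERMINED
        m_inherited = f_inherited = None
    elif m_inherited is None or f_inherited is None:
        status = UNDETERMINED
    elif m_inherited and f_inherited:
        status = AFFECTED_COMPOUND  # refined to hom by the caller if same locus
    elif m_inherited or f_inherited:
        status = CARRIER
    else:
        status = UNAFFECTED

    breakpoints = ([("mother",) + bp for bp in m_bps]
                   + [("father",) + bp for bp in p_bps])
    return EmbryoInheritance(
        embryo_id, snp_ids, positions, m_assign, p_assign,
        m_blocks, p_blocks, n_used, m_inherited, f_inherited, status,
        breakpoints, m_noise + p_noise)


def _gene_midpoint(panel: TargetPanel) -> int:
    regions = panel.gene_regions
    if not regions:
        return 0
    return (min(r.start for r in regions) + max(r.end for r in regions)) // 2


def _blocks(assign: Sequence[str], positions: Sequence[int], min_block: int
            ) -> tuple[list[tuple[str, int, int]], list[tuple[int, int]], int]:
    """Runs of consistent assignment (ignoring '-') → blocks of length
    ≥ min_block; shorter runs are noise.  Returns (blocks, breakpoints as
    (left pos, right pos) between adjacent kept blocks, n noise flags)."""
    idx = [i for i, a in enumerate(assign) if a != "-"]
    runs: list[tuple[str, list[int]]] = []
    for i in idx:
        if runs and runs[-1][0] == assign[i]:
            runs[-1][1].append(i)
        else:
            runs.append((assign[i], [i]))
    noise = sum(1 for label, members in runs if len(members) < min_block)
    kept = [(label, members) for label, members in runs
            if len(members) >= min_block]
    # merge adjacent kept runs with the same label (separated only by noise)
    blocks: list[tuple[str, list[int]]] = []
    for label, members in kept:
        if blocks and blocks[-1][0] == label:
            blocks[-1][1].extend(members)
        else:
            blocks.append((label, list(members)))
    out_blocks = [(label, members[0], members[-1]) for label, members in blocks]
    bps = []
    for (l1, m1), (l2, m2) in zip(blocks[:-1], blocks[1:]):
        bps.append((positions[m1[-1]], positions[m2[0]]))
    return out_blocks, bps, noise


def _mutation_inherited(blocks: list[tuple[str, int, int]],
                        positions: Sequence[int], gene_pos: int,
                        linked_label: str) -> bool | None:
    """Whether the mutation-linked haplotype was inherited, from the block
    containing (or nearest to) the gene; None when no blocks exist."""
    if not blocks:
        return None
    def distance(block):
        _, i0, i1 = block
        lo, hi = positions[i0], positions[i1]
        if lo <= gene_pos <= hi:
            return 0
        return min(abs(gene_pos - lo), abs(gene_pos - hi))
    label = min(blocks, key=distance)[0]
    return label == linked_label


def detect_recombination(inheritance: EmbryoInheritance,
                         min_block: int = 3) -> list[tuple[str, int, int]]:
    """Breakpoints between adjacent runs of length ≥ min_block with
    different haplotype labels (recomputed from the per-SNP assignments)."""
    m_blocks, m_bps, _ = _blocks(inheritance.maternal_assign,
                                 inheritance.positions, min_block)
    p_blocks, p_bps, _ = _blocks(inheritance.paternal_assign,
                                 inheritance.positions, min_block)
    return ([("mother",) + bp for bp in m_bps]
            + [("father",) + bp for bp in p_bps])


@dataclass
class ConcordanceReport:
    per_embryo: dict[str, str]  # agree | disagree | undetermined
    n_comparable: int
    n_agree: int

    @property
    def fraction(self) -> float | None:
        if self.n_comparable == 0:
            return None
        return self.n_agree / self.n_comparable


def concordance(direct_statuses: Mapping[str, str],
                linkage_statuses: Mapping[str, str]) -> ConcordanceReport:
    """Per-embryo agreement between direct genotyping and linkage analysis;
    embryos undetermined on either side are excluded from the denominator.
    The two affected classes are treated as equivalent (linkage alone cannot
    distinguish a homozygote from a compound heterozygote)."""
    per_embryo = {}
    n_comp = n_agree = 0
    affected = {AFFECTED_HOM, AFFECTED_COMPOUND}
    for embryo in sorted(set(direct_statuses) | set(linkage_statuses)):
        d = direct_statuses.get(embryo, UNDETERMINED)
        l = linkage_statuses.get(embryo, UNDETERMINED)
        if UNDETERMINED in (d, l):
            per_embryo[embryo] = "undetermined"
            continue
        n_comp += 1
        same = d == l or (d in affected and l in affected)
        per_embryo[embryo] = "agree" if same else "disagree"
        n_agree += int(same)
    return ConcordanceReport(per_embryo, n_comp, n_agree)
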