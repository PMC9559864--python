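"""Direct genotyping of hotspot pathogenic loci and panel SNPs from deep
on-target reads.

The caller is deliberately simple, as appropriate for ultra-deep amplicon
data: per site, alleles are ranked by read depth; the minor allele ratio
(MAR, second-highest depth / total) decides zygosity against a threshold
(5% in the clinical workflow, 10% in the cell-line validation workflow),
gated on a minimum depth of 100×.  Indel alleles are counted as their own
string keys in the pileup, alongside the four bases.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .models import (
    AFFECTED_COMPOUND,
    AFFECTED_HOM,
    CARRIER,
    UNAFFECTED,
    UNDETERMINED,
    DiseaseStatus,
    GenotypeCall,
    HotspotLocus,
    SiteAlleleDepth,
    SnpSite,
)

CLINICAL_HOM_MAR = 0.05
VALIDATION_HOM_MAR = 0.10
MIN_DEPTH = 100


def pileup(allele_observations: Iterable[tuple[str, str]],
           sites: Sequence[SnpSite | HotspotLocus]) -> list[SiteAlleleDepth]:
    """Tally per-site allele depths from (site_id, observed allele) pairs.

    Every requested site gets an entry; an uncovered site has total depth 0.
    """
    depths: dict[str, dict[str, int]] = {}
    for site in sites:
        sid = site.id if isinstance(site, SnpSite) else site.name
        depths[sid] = {}
    for sid, allele in allele_observations:
        if sid not in depths:
            continue  # observation outside the requested site list
        d = depths[sid]
        d[allele] = d.get(allele, 0) + 1
    out = []
    for site in sites:
        sid = site.id if isinstance(site, SnpSite) else site.name
        out.append(SiteAlleleDepth(sid, depths[sid], site.locus.chrom,
                                   site.position))
    return out


def call_genotype(sad: SiteAlleleDepth, min_depth: int = MIN_DEPTH,
                  hom_mar_threshold: float = CLINICAL_HOM_MAR) -> GenotypeCall:
    """Depth-gated MAR genotype call.

    depth < min_depth ⇒ no_call; MAR < threshold ⇒ homozygous for the major
    allele; otherwise heterozygous for the top two alleles.  Third and lower
    alleles count toward the total depth but never toward the genotype.
    """
    depth = sad.total_depth
    if depth < min_depth:
        flags = ("low_depth",) if depth > 0 else ("low_depth", "no_amplification")
        return GenotypeCall(sad.site_id, None, "no_call", sad.mar, depth, flags)
    mar = sad.mar
    top = sad.top_alleles(2)
    if mar < hom_mar_threshold:
        return GenotypeCall(sad.site_id, (top[0], top[0]), "hom", mar, depth)
    return GenotypeCall(sad.site_id, (top[0], top[1]), "het", mar, depth)


def classify_disease(hotspot_calls: Mapping[str, GenotypeCall],
                     hotspots: Sequence[HotspotLocus],
                     parental_hotspots: Iterable[str] = ()) -> DiseaseStatus:
    """Embryo disease status from the genotype calls at the hotspot loci.

    Pathogenic-allele dosage decides the class: zero ⇒ unaffected, one
    (heterozygous) ⇒ carrier, homozygous alt at one locus ⇒ affected
    homozygote, heterozygous alt at two loci ⇒ affected compound
    heterozygote.  A no_call at a known parental pathogenic locus makes the
    status undetermined rather than guessed.
    """
    parental = set(parental_hotspots)
    pathogenic_het = []
    pathogenic_hom = []
    supporting = []
    for h in hotspots:
        call = hotspot_calls.get(h.name)
        if call is None or call.zygosity == "no_call":
            if h.name in parental or not parental:
                return DiseaseStatus(UNDETERMINED,
                                     [c for c in hotspot_calls.values()])
            continue
        supporting.append(call)
        if call.has_allele(h.alt_allele):
            if call.zygosity == "hom" and call.alleles[0] == h.alt_allele:
                pathogenic_hom.append(h.name)
            else:
                pathogenic_het.append(h.name)
    if pathogenic_hom:
        return DiseaseStatus(AFFECTED_HOM, supporting)
    if len(pathogenic_het) >= 2:
        return DiseaseStatus(AFFECTED_COMPOUND, supporting)
    if len(pathogenic_het) == 1:
        return DiseaseStatus(CARRIER, supporting)
    return DiseaseStatus(UNAFFECTED, supporting)


def detect_ado(embryo_sad: SiteAlleleDepth, father_call: GenotypeCall,
               mother_call: GenotypeCall, min_depth: int = MIN_DEPTH,
               presence_frac: float = 0.02) -> bool:
    """Flag allele dropout at a trio site.

    ADO is flagged when an allele that is *obligate* from the parental
    genotypes (both parents homozygous for different alleles ⇒ the embryo
    must be heterozygous) is effectively absent from the embryo's depths
    (< ``presence_frac`` of total), or when the site failed to amplify in
    the embryo despite amplifying in both parents.
    """
    total = embryo_sad.total_depth
    parents_ok = (father_call.zygosity != "no_call"
                  and mother_call.zygosity != "no_call")
    if total == 0:
        return parents_ok
    if not parents_ok:
        return False
    if (father_call.zygosity == "hom" and mother_call.zygosity == "hom"
            and father_call.alleles[0] != mother_call.alleles[0]):
        for obligate in (father_call.alleles[0], mother_call.alleles[0]):
            if embryo_sad.depth_by_allele.get(obligate, 0) < presence_frac * total:
                return True
    return False
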