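"""Informative-SNP selection, trio phasing, embryo inference, recombination."""

import numpy as np
import pytest

from tags_pgt.genotype import call_genotype
from tags_pgt.linkage import (
    MendelianInconsistencyError,
    concordance,
    detect_recombination,
    infer_embryo,
    phase_trio,
    select_informative_snps,
)
from tags_pgt.models import (
    AFFECTED_COMPOUND,
    CARRIER,
    UNAFFECTED,
    UNDETERMINED,
    GenotypeCall,
)
from tags_pgt.simulate import SimConfig, simulate_allele_depths, simulate_family

from conftest import make_snp_panel


def gt(site_id, a1, a2):
    zyg = "hom" if a1 == a2 else "het"
    return GenotypeCall(site_id, (a1, a2), zyg, 0.4 if zyg == "het" else 0.01,
                        5000)


def trio_calls(panel, father_haps, mother_haps, proband_pairs):
    """Build call dicts from per-SNP allele strings."""
    father, mother, proband = {}, {}, {}
    for i, s in enumerate(panel.snp_sites):
        father[s.id] = gt(s.id, *father_haps[i])
        mother[s.id] = gt(s.id, *mother_haps[i])
        proband[s.id] = gt(s.id, *proband_pairs[i])
    return father, mother, proband


class TestInformativeSelection:
    def test_rule_applied_per_parent(self, panel):
        snps = panel.snp_sites
        father = {snps[0].id: gt(snps[0].id, "A", "G"),
                  snps[1].id: gt(snps[1].id, "A", "G"),
                  snps[2].id: gt(snps[2].id, "A", "A")}
        mother = {snps[0].id: gt(snps[0].id, "A", "A"),
                  snps[1].id: gt(snps[1].id, "A", "G"),
                  snps[2].id: gt(snps[2].id, "A", "A")}
        proband = {snps[0].id: gt(snps[0].id, "A", "A"),
                   snps[1].id: gt(snps[1].id, "A", "G"),
                   snps[2].id: gt(snps[2].id, "A", "A")}
        out = select_informative_snps(father, mother, proband, panel)
        assert [i.snp.id for i in out] == [snps[0].id]
        assert out[0].informs_father and not out[0].informs_mother

    def test_proband_het_excluded(self, panel):
        s = panel.snp_sites[0]
        out = select_informative_snps({s.id: gt(s.id, "A", "G")},
                                      {s.id: gt(s.id, "A", "G")},
                                      {s.id: gt(s.id, "A", "G")}, panel)
        assert out == []

    def test_no_het_parent_excluded(self, panel):
        s = panel.snp_sites[0]
        out = select_informative_snps({s.id: gt(s.id, "A", "A")},
                                      {s.id: gt(s.id, "A", "A")},
                                      {s.id: gt(s.id, "A", "A")}, panel)
        assert out == []


class TestPhasing:
    def test_transmitted_allele_defines_linked_haplotype(self, panel):
        s = panel.snp_sites[0]
        father = {s.id: gt(s.id, "A", "A")}
        mother = {s.id: gt(s.id, "A", "G")}
        proband = {s.id: gt(s.id, "A", "A")}
        informative = select_informative_snps(father, mother, proband, panel)
        phased = phase_trio(father, mother, proband, informative)
        assert phased.M1[s.id] == "A"
        assert phased.M2[s.id] == "G"

    def test_mendelian_inconsistency_raises(self, panel):
        snps = panel.snp_sites[:5]
        father = {s.id: gt(s.id, "A", "G") for s in snps}
        mother = {s.id: gt(s.id, "A", "A") for s in snps}
        proband = {s.id: gt(s.id, "C", "C") for s in snps}  # impossible
        informative = select_informative_snps(father, mother, proband, panel)
        with pytest.raises(MendelianInconsistencyError):
            phase_trio(father, mother, proband, informative)

    def test_simulated_family_phases_to_truth(self, panel):
        """Proband-anchored phasing recovers the simulated mutation-linked
        parental haplotypes at every informative SNP."""
        cfg = SimConfig(seed=2, n_embryos=2, ado_rate=0.0,
                        recombination_rate=0.0, pref_amp_rho=0.01)
        truth = simulate_family(cfg, panel)
        depths = simulate_allele_depths(truth, cfg)
        calls = {s: {x.site_id: call_genotype(x) for x in sads}
                 for s, sads in depths.items()}
        father, mother = calls[truth.father.sample_id], calls[truth.mother.sample_id]
        proband = calls[truth.proband.sample_id]
        informative = select_informative_snps(father, mother, proband, panel)
        phased = phase_trio(father, mother, proband, informative)
        m_linked = truth.mother_haps[truth.mother_mut_hap]
        f_linked = truth.father_haps[truth.father_mut_hap]
        for sid in phased.maternal_informative:
            assert phased.M1[sid] == m_linked[sid]
        for sid in phased.paternal_informative:
            assert phased.F1[sid] == f_linked[sid]


def make_phased_fixture(panel, n=19):
    """A hand-built phased trio over n SNPs: the first 3 inform the father
    (father het A/G, mother hom A), the rest inform the mother (mother het
    A/G, father hom A); the proband is hom A throughout, so M1 = F1 = A."""
    snps = panel.snp_sites[:n]
    father, mother, proband = {}, {}, {}
    for i, s in enumerate(snps):
        if i < 3:
            father[s.id] = gt(s.id, "A", "G")
            mother[s.id] = gt(s.id, "A", "A")
        else:
            father[s.id] = gt(s.id, "A", "A")
            mother[s.id] = gt(s.id, "A", "G")
        proband[s.id] = gt(s.id, "A", "A")
    informative = select_informative_snps(father, mother, proband, panel)
    phased = phase_trio(father, mother, proband, informative)
    return snps, phased


class TestEmbryoInference:
    def test_clean_m1_f2_embryo_is_carrier(self, panel):
        snps, phased = make_phased_fixture(panel)
        # embryo inherits M1 (A, mutation-linked) + F2 (G at the 3 info sites)
        embryo = {}
        for i, s in enumerate(snps):
            embryo[s.id] = gt(s.id, "A", "G") if i < 3 else gt(s.id, "A", "A")
        inh = infer_embryo(embryo, phased, panel, min_informative=3)
        assert inh.n_informative_used == {"mother": 16, "father": 3}
        assert inh.maternal_mutation_inherited is True
        assert inh.paternal_mutation_inherited is False
        assert inh.inferred_disease_status == CARRIER
        assert inh.recombination_breakpoints == []

    def test_all_no_call_is_undetermined(self, panel):
        snps, phased = make_phased_fixture(panel)
        embryo = {s.id: GenotypeCall(s.id, None, "no_call", 0.0, 0)
                  for s in snps}
        inh = infer_embryo(embryo, phased, panel)
        assert inh.inferred_disease_status == UNDETERMINED

    def test_recombination_blocks_11_and_5(self, panel):
        """Maternal assignment 11×M1 then 5×M2 → one breakpoint, blocks of
        11 and 5 SNPs, mutation assigned from the block nearest the gene."""
        snps, phased = make_phased_fixture(panel, n=19)
        embryo = {}
        for i, s in enumerate(snps):
            if i < 3:
                # paternal-informative sites follow F1; mother contributes A
                embryo[s.id] = gt(s.id, "A", "A")
            else:
                maternal = "A" if i < 14 else "G"  # 11 × M1 then 5 × M2
                embryo[s.id] = gt(s.id, maternal, "A")
        inh = infer_embryo(embryo, phased, panel, min_informative=3)
        labels = [b[0] for b in inh.maternal_blocks]
        sizes = [b[2] - b[1] + 1 for b in inh.maternal_blocks]
        assert labels == ["M1", "M2"]
        assert sizes == [11, 5]
        assert len([bp for bp in inh.recombination_breakpoints
                    if bp[0] == "mother"]) == 1
        # gene sits beyond the last SNP → the M2 block decides inheritance
        assert inh.maternal_mutation_inherited is False

    def test_single_flip_is_noise_not_recombination(self, panel):
        snps, phased = make_phased_fixture(panel, n=19)
        embryo = {}
        for i, s in enumerate(snps):
            if i < 3:
                embryo[s.id] = gt(s.id, "A", "A")
            else:
                maternal = "G" if i == 8 else "A"  # lone M2 in an M1 run
                embryo[s.id] = gt(s.id, maternal, "A")
        inh = infer_embryo(embryo, phased, panel, min_informative=3)
        assert [b[0] for b in inh.maternal_blocks] == ["M1"]
        assert not [bp for bp in inh.recombination_breakpoints
                    if bp[0] == "mother"]
        assert inh.noise_flags >= 1
        assert detect_recombination(inh) == inh.recombination_breakpoints


class TestConcordance:
    def test_53_of_54(self):
        direct = {f"E{i}": CARRIER for i in range(54)}
        linkage = dict(direct)
        linkage["E7"] = UNAFFECTED
        rep = concordance(direct, linkage)
        assert rep.n_comparable == 54
        assert rep.n_agree == 53
        assert rep.fraction == pytest.approx(53 / 54)

    def test_empty_report(self):
        rep = concordance({}, {})
        assert rep.fraction is None
        assert rep.per_embryo == {}

    def test_undetermined_excluded_from_denominator(self):
        direct = {"E1": CARRIER, "E2": CARRIER}
        linkage = {"E1": CARRIER, "E2": UNDETERMINED}
        rep = concordance(direct, linkage)
        assert rep.n_comparable == 1
        assert rep.per_embryo["E2"] == "undetermined"


class TestSimulationConsistency:
    def test_linkage_matches_truth_and_direct_on_clean_simulations(self):
        """200 ADO-free, error-free-phase embryos without recombination:
        inferred status equals the simulated truth for every embryo."""
        panel = make_snp_panel(65, spacing=2000, maf=0.45)
        n_total = 0
        n_match = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_embryos=20, ado_rate=0.0,
                            recombination_rate=0.0, pref_amp_rho=0.01,
                            father_hotspot="hotA", mother_hotspot="hotB")
            truth = simulate_family(cfg, panel)
            depths = simulate_allele_depths(truth, cfg)
            calls = {s: {x.site_id: call_genotype(x) for x in sads}
                     for s, sads in depths.items()}
            father = calls[truth.father.sample_id]
            mother = calls[truth.mother.sample_id]
            proband = calls[truth.proband.sample_id]
            informative = select_informative_snps(father, mother, proband, panel)
            phased = phase_trio(father, mother, proband, informative)
            for embryo in truth.embryos:
                inh = infer_embryo(calls[embryo.sample_id], phased, panel,
                                   min_informative=5)
                n_total += 1
                if inh.inferred_disease_status == embryo.disease_status:
                    n_match += 1
        assert n_total == 200
        assert n_match == n_total

    def test_genotyping_noise_tolerance(self, rng):
        """1% per-site genotype errors: disease-genotype accuracy ≥99%
        with ≥10 informative SNPs per side (1000 embryos)."""
        panel = make_snp_panel(120, spacing=2000, maf=0.45)
        n_eval = 0
        n_correct = 0
        for seed in range(5):
            cfg = SimConfig(seed=100 + seed, n_embryos=200, ado_rate=0.0,
                            recombination_rate=0.0, pref_amp_rho=0.01,
                            father_hotspot="hotA", mother_hotspot="hotB")
            truth = simulate_family(cfg, panel)
            # perfect parental/proband calls; noisy embryo calls
            def clean_calls(sample):
                return {sid: gt(sid, *sample.genotypes[sid])
                        for sid in truth.site_ids}
            father = clean_calls(truth.father)
            mother = clean_calls(truth.mother)
            proband = clean_calls(truth.proband)
            informative = select_informative_snps(father, mother, proband, panel)
            phased = phase_trio(father, mother, proband, informative)
            for embryo in truth.embryos:
                calls = {}
                for sid in truth.site_ids:
                    a1, a2 = embryo.genotypes[sid]
                    if rng.random() < 0.01:  # flip zygosity at this site
                        a2 = a1 if a1 != a2 else ("G" if a1 == "A" else "A")
                    calls[sid] = gt(sid, a1, a2)
                inh = infer_embryo(calls, phased, panel, min_informative=10)
                if inh.inferred_disease_status == UNDETERMINED:
                    continue
                n_eval += 1
                if inh.inferred_disease_status == embryo.disease_status:
                    n_correct += 1
        assert n_eval >= 500
        assert n_correct / n_eval >= 0.99
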