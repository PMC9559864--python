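"""Per-embryo and cohort reporting: merged PGT-A/M verdicts, cohort
statistics, exact binomial confidence intervals, and the end-to-end
simulated-cohort pipeline driver."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from . import cnv as cnv_mod
from . import genotype as gt_mod
from . import linkage as lk_mod
from . import simulate as sim_mod
from .genome import scaled_genome
from .models import (
    AFFECTED_COMPOUND,
    AFFECTED_HOM,
    DISEASE_CLASSES,
    UNDETERMINED,
    CohortSummary,
    EmbryoReport,
    TargetPanel,
)


def percent(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (53.7 for 29/54)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    d = Decimal(count) * 100 / Decimal(denominator)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def clopper_pearson(successes: int, n: int, conf: float = 0.95
                    ) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval via
    beta quantiles; (n, n) has upper bound exactly 1 and lower (α/2)^(1/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def chromosomal_class(report: EmbryoReport) -> str:
    """aneuploidy > cnv > normal (an embryo with both counts as aneuploid)."""
    if report.has_aneuploidy:
        return "aneuploidy"
    if report.cnv_calls:
        return "cnv"
    return "normal"


def transferable_rate(reports: list[EmbryoReport],
                      allow_carrier: bool = True) -> dict[str, float]:
    """Fractions of embryos transferable on disease grounds alone and after
    also requiring a normal chromosomal result."""
    if not reports:
        return {"n": 0, "disease_only": float("nan"), "combined": float("nan")}
    for r in reports:
        r.allow_carrier = allow_carrier
    n = len(reports)
    disease_free = sum(r.disease_free for r in reports)
    combined = sum(r.transferable for r in reports)
    return {"n": n, "n_disease_free": disease_free, "n_combined": combined,
            "disease_only": disease_free / n, "combined": combined / n}


def summarize_cohort(reports: list[EmbryoReport]) -> CohortSummary:
    """Counts and half-up percentages per disease and chromosomal class."""
    n = len(reports)
    if n == 0:
        return CohortSummary(0, {}, {}, {}, {}, float("nan"), float("nan"))
    disease_counts = {c: 0 for c in DISEASE_CLASSES}
    for r in reports:
        disease_counts[r.direct_status] += 1
    chrom_counts = {"normal": 0, "aneuploidy": 0, "cnv": 0}
    for r in reports:
        chrom_counts[chromosomal_class(r)] += 1
    rates = transferable_rate(reports)
    return CohortSummary(
        n_embryos=n,
        disease_counts=disease_counts,
        disease_percent={c: percent(k, n) for c, k in disease_counts.items()},
        chromosomal_counts=chrom_counts,
        chromosomal_percent={c: percent(k, n) for c, k in chrom_counts.items()},
        transferable_rate_disease_only=rates["disease_only"],
        transferable_rate_combined=rates["combined"],
    )


@dataclass
class ExternalConcordance:
    fraction: float | None
    n_comparable: int
    n_agree: int
    discordant: list[tuple[str, object, object]] = field(default_factory=list)


def concordance_vs_external(calls: dict[str, object],
                            external_calls: dict[str, object]
                            ) -> ExternalConcordance:
    """Agreement with an external call set; externally undetermined embryos
    (value None or "undetermined") are excluded from the denominator."""
    n_comp = n_agree = 0
    discordant = []
    for embryo in sorted(calls):
        ext = external_calls.get(embryo)
        if ext is None or ext == UNDETERMINED:
            continue
        n_comp += 1
        if calls[embryo] == ext:
            n_agree += 1
        else:
            discordant.append((embryo, calls[embryo], ext))
    frac = n_agree / n_comp if n_comp else None
    return ExternalConcordance(frac, n_comp, n_agree, discordant)


# ---------------------------------------------------------------------------
# End-to-end simulated-cohort pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    truth: sim_mod.FamilyTruth
    genotype_calls: dict
    direct_statuses: dict[str, str]
    linkage_statuses: dict[str, str]
    embryo_reports: list[EmbryoReport]
    summary: CohortSummary
    linkage_concordance: lk_mod.ConcordanceReport


def run_pipeline(config: sim_mod.SimConfig, panel: TargetPanel | None = None,
                 min_informative: int = lk_mod.MIN_INFORMATIVE_PERMISSIVE,
                 cnv_genome_scale: float | None = None,
                 reads_per_window: int = 100_000,
                 overlap: int = 20_000,
                 skip_cnv: bool = False) -> PipelineResult:
    """Simulate one family and run both analysis arms end to end.

    The monogenic arm runs at full panel scale; the chromosomal arm runs on
    a genome scaled by ``cnv_genome_scale`` (default the config's
    ``genome_scale``) so the whole pipeline stays fast.  Deterministic given
    the config seed.
    """
    from .io import builtin_panel

    panel = panel or builtin_panel()
    rng = config.rng()
    truth = sim_mod.simulate_family(config, panel, rng=rng)
    depths = sim_mod.simulate_allele_depths(truth, config, rng=rng)

    calls = {
        sample: {sad.site_id: gt_mod.call_genotype(sad) for sad in sads}
        for sample, sads in depths.items()
    }
    manifest = truth.manifest
    father_id = manifest.member("father").sample_id
    mother_id = manifest.member("mother").sample_id
    proband_id = manifest.member("proband").sample_id
    parental_hotspots = set(manifest.parental_hotspots.values())

    direct, linkage_status = {}, {}
    informative = lk_mod.select_informative_snps(
        calls[father_id], calls[mother_id], calls[proband_id], panel)
    phased = lk_mod.phase_trio(calls[father_id], calls[mother_id],
                               calls[proband_id], informative)
    same_locus = (config.father_hotspot == config.mother_hotspot)
    for embryo in truth.embryos:
        eid = embryo.sample_id
        direct[eid] = gt_mod.classify_disease(
            calls[eid], panel.hotspot_loci, parental_hotspots).status
        inh = lk_mod.infer_embryo(calls[eid], phased, panel, embryo_id=eid,
                                  min_informative=min_informative)
        status = inh.inferred_disease_status
        if status == AFFECTED_COMPOUND and same_locus:
            status = AFFECTED_HOM
        linkage_status[eid] = status

    reports = []
    if skip_cnv:
        windows = None
    else:
        scale = config.genome_scale if cnv_genome_scale is None else cnv_genome_scale
        sizes = scaled_genome(scale, include_y=config.sex != "female")
        windows = cnv_mod.build_windows(sizes, read_len=config.read_len,
                                        reads_per_window=reads_per_window,
                                        overlap=overlap)
    for k, embryo in enumerate(truth.embryos):
        eid = embryo.sample_id
        chrom_calls: dict[str, str] = {}
        cnv_calls: list = []
        if windows is not None:
            aneu = config.embryo_aneuploidies.get(k, [])
            cnvs = config.embryo_cnv_events.get(k, [])
            counted = sim_mod.simulate_window_counts(
                windows, config, rng=rng, cnv_events=cnvs, aneuploidies=aneu)
            result = cnv_mod.call_sample(counted)
            chrom_calls = {c.chrom: c.call for c in result["chromosome_calls"]}
            aneuploid = {c.chrom for c in result["chromosome_calls"]
                         if c.call not in ("disomy", "expected")}
            cnv_calls = [c for c in result["cnvs"]
                         if c.interval.chrom not in aneuploid]
        reports.append(EmbryoReport(
            embryo_id=eid, direct_status=direct[eid],
            linkage_status=linkage_status[eid],
            chromosome_calls=chrom_calls, cnv_calls=cnv_calls,
            qc={"n_informative": None}))

    summary = summarize_cohort(reports)
    link_conc = lk_mod.concordance(direct, linkage_status)
    return PipelineResult(truth, calls, direct, linkage_status, reports,
                          summary, link_conc)


def summary_to_dict(result: PipelineResult) -> dict:
    s = result.summary
    return {
        "n_embryos": s.n_embryos,
        "disease_counts": s.disease_counts,
        "disease_percent": s.disease_percent,
        "chromosomal_counts": s.chromosomal_counts,
        "chromosomal_percent": s.chromosomal_percent,
        "transferable_rate_disease_only": s.transferable_rate_disease_only,
        "transferable_rate_combined": s.transferable_rate_combined,
        "direct_statuses": result.direct_statuses,
        "linkage_statuses": result.linkage_statuses,
        "linkage_vs_direct_concordance": result.linkage_concordance.fraction,
        "embryos": [
            {
                "embryo_id": r.embryo_id,
                "direct_status": r.direct_status,
                "linkage_status": r.linkage_status,
                "chromosome_calls": r.chromosome_calls,
                "cnvs": [c.karyotype_line() for c in r.cnv_calls],
                "transferable": r.transferable,
            }
            for r in result.embryo_reports
        ],
    }
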