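"""Readers and writers for the standard formats the pipeline touches.

BED is 0-based half-open; SAM and VCF positions are 1-based and converted at
this boundary; the sites TSVs use 1-based positions (VCF-like).  SAM/BAM and
VCF go through pysam.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .genome import HG19_SIZES, VALID_CHROMS
from .models import (
    ALIGNMENT_COLUMNS,
    AlignmentRecord,
    GenomicInterval,
    GenotypeCall,
    HotspotLocus,
    SampleInfo,
    SampleManifest,
    SnpSite,
    TargetPanel,
)


class PanelParseError(ValueError):
    pass


def _open_lines(path) -> list[str]:
    return Path(path).read_text().splitlines()


def load_panel(bed_path, snp_tsv_path, hotspot_tsv_path=None) -> TargetPanel:
    """Load a target panel from a BED of gene regions plus a SNP table
    (columns id, chrom, pos, ref, alt, maf; pos 1-based) and an optional
    hotspot table (name, chrom, pos, ref, alt)."""
    regions: list[GenomicInterval] = []
    for i, line in enumerate(_open_lines(bed_path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PanelParseError(f"{bed_path}:{i}: expected >=3 BED columns")
        try:
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise PanelParseError(f"{bed_path}:{i}: {exc}") from exc
        regions.append(iv)

    snps: list[SnpSite] = []
    for i, line in enumerate(_open_lines(snp_tsv_path), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            raise PanelParseError(f"{snp_tsv_path}:{i}: expected 6 columns")
        sid, chrom, pos, ref, alt, maf = parts
        try:
            snps.append(SnpSite(sid, GenomicInterval(chrom, int(pos) - 1, int(pos)),
                                ref, alt, float(maf)))
        except ValueError as exc:
            raise PanelParseError(f"{snp_tsv_path}:{i}: {exc}") from exc

    hotspots: list[HotspotLocus] = []
    if hotspot_tsv_path is not None:
        for i, line in enumerate(_open_lines(hotspot_tsv_path), start=1):
            if not line.strip() or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise PanelParseError(f"{hotspot_tsv_path}:{i}: expected 5 columns")
            name, chrom, pos, ref, alt = parts
            try:
                hotspots.append(HotspotLocus(
                    name, GenomicInterval(chrom, int(pos) - 1, int(pos) - 1 + len(ref)),
                    ref, alt))
            except ValueError as exc:
                raise PanelParseError(f"{hotspot_tsv_path}:{i}: {exc}") from exc

    return TargetPanel(regions, snps, hotspots)


def builtin_panel() -> TargetPanel:
    """The shipped β-thalassemia panel: HBB region, 65 flanking SNPs and the
    11 Southern-China hotspot loci.  Coordinates are reconstructed stand-ins
    (see the data-file headers)."""
    root = resources.files("tags_pgt") / "data"
    return load_panel(root / "hbb_panel.bed", root / "hbb_snps.tsv",
                      root / "hbb_hotspots.tsv")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path, min_mapq: int = 1) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from SAM/BAM (via pysam) or the documented
    TSV dialect (read_id, chrom, pos[1-based], aligned_len, is_unique,
    is_duplicate, template_len).

    Uniqueness rule for SAM: primary alignment with MAPQ >= ``min_mapq``.
    """
    path = Path(path)
    if path.suffix in (".sam", ".bam", ".cram"):
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                chrom = rec.reference_name
                if chrom not in VALID_CHROMS:
                    raise ValueError(
                        f"alignment on contig {chrom!r} absent from hg19 naming")
                alen = rec.reference_length or rec.query_length or 0
                if alen <= 0:
                    continue
                tlen = abs(rec.template_length) or alen
                yield AlignmentRecord(
                    read_id=rec.query_name,
                    interval=GenomicInterval(chrom, rec.reference_start,
                                             rec.reference_start + alen),
                    aligned_len=alen,
                    is_unique=(not rec.is_secondary and not rec.is_supplementary
                               and rec.mapping_quality >= min_mapq),
                    is_duplicate=rec.is_duplicate,
                    template_len=tlen,
                )
    else:
        for i, line in enumerate(_open_lines(path), start=1):
            if not line.strip() or line.startswith("#") or line.startswith("read_id\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{i}: expected 7 columns")
            rid, chrom, pos, alen, uniq, dup, tlen = parts
            if chrom not in VALID_CHROMS:
                raise ValueError(
                    f"{path}:{i}: contig {chrom!r} absent from hg19 naming")
            alen = int(alen)
            yield AlignmentRecord(
                rid, GenomicInterval(chrom, int(pos) - 1, int(pos) - 1 + alen),
                alen, uniq in ("1", "True", "true"),
                dup in ("1", "True", "true"), int(tlen))


def read_alignment_table(path, min_mapq: int = 1) -> pd.DataFrame:
    """Bulk alignment-table reader; the TSV path is vectorized (the
    per-record streaming API is `read_alignments`)."""
    path = Path(path)
    if path.suffix in (".sam", ".bam", ".cram"):
        from .models import alignments_to_frame
        return alignments_to_frame(read_alignments(path, min_mapq=min_mapq))
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"read_id": str, "chrom": str})
    bad = set(df["chrom"].unique()) - VALID_CHROMS
    if bad:
        raise ValueError(f"contigs absent from hg19 naming: {sorted(bad)}")
    df["start"] = df["pos"] - 1
    df["is_unique"] = df["is_unique"].astype(bool)
    df["is_duplicate"] = df["is_duplicate"].astype(bool)
    return df[["read_id", "chrom", "start", "aligned_len", "is_unique",
               "is_duplicate", "template_len"]]


def write_alignment_table(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["pos"] = out["start"] + 1
    out["is_unique"] = out["is_unique"].astype(int)
    out["is_duplicate"] = out["is_duplicate"].astype(int)
    out[["read_id", "chrom", "pos", "aligned_len", "is_unique",
         "is_duplicate", "template_len"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_genotypes_vcf(calls: dict[str, list[GenotypeCall]], panel: TargetPanel,
                        path) -> None:
    """Write per-sample genotype calls at panel sites to VCF 4.2.

    FORMAT carries GT, DP (depth) and MR (minor allele ratio); a call whose
    MAR is unavailable gets the missing-value token.
    """
    samples = list(calls)
    header = pysam.VariantHeader()
    for chrom, length in HG19_SIZES.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("MR", 1, "Float", "Minor allele ratio")
    for s in samples:
        header.add_sample(s)

    by_site = {site.id if isinstance(site, SnpSite) else site.name: site
               for site in panel.all_sites}
    site_calls: dict[str, dict[str, GenotypeCall]] = {}
    for sample, clist in calls.items():
        for c in clist:
            site_calls.setdefault(c.site_id, {})[sample] = c

    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(site_calls, key=lambda sid: (
            by_site[sid].locus.chrom, by_site[sid].position))
        for sid in order:
            site = by_site[sid]
            rec = out.new_record(
                contig=site.locus.chrom, start=site.position,
                alleles=(site.ref_allele, site.alt_allele), id=sid)
            for sample in samples:
                c = site_calls[sid].get(sample)
                fmt = rec.samples[sample]
                if c is None or c.zygosity == "no_call" or c.alleles is None:
                    fmt["GT"] = (None, None)
                else:
                    idx = {site.ref_allele: 0, site.alt_allele: 1}
                    gt = tuple(sorted((idx.get(a) for a in c.alleles),
                                      key=lambda v: (v is None, v)))
                    fmt["GT"] = gt
                if c is not None:
                    fmt["DP"] = c.depth
                    if c.mar == c.mar:  # not NaN
                        fmt["MR"] = float(c.mar)
            out.write(rec)


def read_genotypes_vcf(path, panel: TargetPanel) -> dict[str, list[GenotypeCall]]:
    by_pos = {(s.locus.chrom, s.position): s for s in panel.all_sites}
    out: dict[str, list[GenotypeCall]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            out[s] = []
        for rec in vcf:
            site = by_pos.get((rec.contig, rec.start))
            sid = rec.id or (site.id if isinstance(site, SnpSite) else site.name)
            for s in samples:
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                depth = fmt.get("DP") or 0
                mar = fmt.get("MR")
                mar = float(mar) if mar is not None else float("nan")
                if gt is None or any(a is None for a in gt):
                    out[s].append(GenotypeCall(sid, None, "no_call", mar, depth))
                else:
                    alleles = tuple(rec.alleles[a] for a in gt)
                    zyg = "hom" if alleles[0] == alleles[1] else "het"
                    out[s].append(GenotypeCall(sid, alleles, zyg, mar, depth))
    return out


# ---------------------------------------------------------------------------
# Segments / reports / manifest
# ---------------------------------------------------------------------------

def write_segments_tsv(segments, path) -> None:
    rows = [(s.interval.chrom, s.interval.start, s.interval.end,
             s.mean_copy_ratio, s.n_bins, s.call) for s in segments]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_ratio",
                                "n_bins", "call"]).to_csv(path, sep="\t",
                                                          index=False)


def read_segments_tsv(path):
    from .cnv import Segment
    df = pd.read_csv(path, sep="\t")
    return [Segment(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                    float(r.copy_ratio), int(r.n_bins), str(r.call))
            for r in df.itertuples(index=False)]


def write_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def read_report_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_depths_tsv(depths: dict[str, list], path) -> None:
    """Per-sample per-site allele depth table (sample, site_id, chrom, pos,
    allele, depth); pos 1-based."""
    rows = []
    for sample, sads in depths.items():
        for sad in sads:
            if not sad.depth_by_allele:
                rows.append((sample, sad.site_id, sad.chrom,
                             (sad.position or 0) + 1, ".", 0))
            for allele, depth in sorted(sad.depth_by_allele.items()):
                rows.append((sample, sad.site_id, sad.chrom,
                             (sad.position or 0) + 1, allele, depth))
    pd.DataFrame(rows, columns=["sample", "site_id", "chrom", "pos",
                                "allele", "depth"]).to_csv(path, sep="\t",
                                                           index=False)


def read_depths_tsv(path) -> dict[str, list]:
    from .models import SiteAlleleDepth
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "site_id": str,
                                            "allele": str})
    out: dict[str, list] = {}
    for (sample, sid), grp in df.groupby(["sample", "site_id"], sort=False):
        d = {str(r.allele): int(r.depth) for r in grp.itertuples(index=False)
             if r.allele != "."}
        out.setdefault(sample, []).append(SiteAlleleDepth(
            str(sid), d, str(grp["chrom"].iloc[0]), int(grp["pos"].iloc[0]) - 1))
    return out


def write_window_counts(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# read_len={profile.read_len} "
                 f"reads_per_window={profile.reads_per_window} "
                 f"overlap={profile.overlap}\n")
        profile.df.to_csv(fh, sep="\t", index=False)


def read_window_counts(path):
    from .cnv import WindowProfile
    meta = {"read_len": 50, "reads_per_window": 100_000, "overlap": 20_000}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                k, v = token.split("=")
                meta[k] = int(v)
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return WindowProfile(df, meta["read_len"], meta["reads_per_window"],
                         meta["overlap"])


def load_manifest(path) -> list[SampleManifest]:
    """Sample manifest TSV: family_id, sample_id, role, hotspot (parents only)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    manifests = []
    for fam, grp in df.groupby("family_id", sort=True):
        members = [SampleInfo(r.sample_id, r.role)
                   for r in grp.itertuples(index=False)]
        hotspots = {r.role: r.hotspot for r in grp.itertuples(index=False)
                    if r.role in ("father", "mother") and r.hotspot}
        manifests.append(SampleManifest(str(fam), members, hotspots))
    return manifests


def write_manifest(manifests: Iterable[SampleManifest], path) -> None:
    rows = []
    for m in manifests:
        for s in m.members:
            rows.append((m.family_id, s.sample_id, s.role,
                         m.parental_hotspots.get(s.role, "")))
    pd.DataFrame(rows, columns=["family_id", "sample_id", "role",
                                "hotspot"]).to_csv(path, sep="\t", index=False)
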