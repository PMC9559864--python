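"""Filter alignments and split them into the on-target (deep amplicon) and
off-target (low-pass genome-wide) fractions.

The mixed library yields one read stream; reads overlapping the target panel
(gene regions, panel SNPs, hotspot loci, each ± a configurable flank) by at
least 1 bp are routed to the monogenic arm, everything else to the
chromosomal arm.  Filtering applies the standard low-pass hygiene rules:
unique, non-duplicate, template ≤ 500 nt (inert for SE50 data, where the
template equals the 50-bp aligned span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import TargetPanel, alignments_to_frame


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return alignments_to_frame(records)


@dataclass
class RoutedReads:
    on_target: pd.DataFrame
    off_target: pd.DataFrame
    per_amplicon_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def n_total(self) -> int:
        return len(self.on_target) + len(self.off_target)


@dataclass
class QcSummary:
    total_reads: int
    frac_wgs: float
    frac_tes: float
    wgs_depth: float
    tes_depth: float
    amplicon_on_target_rate: float
    amplicon_uniformity: float
    warning: str | None = None


def filter_alignments(records, max_template_len: int = 500,
                      require_unique: bool = True,
                      drop_duplicates: bool = True) -> pd.DataFrame:
    """Keep unique, non-duplicate records with template ≤ max_template_len;
    input order is preserved."""
    df = _as_frame(records)
    if df.empty:
        return df
    keep = df["template_len"] <= max_template_len
    if require_unique:
        keep &= df["is_unique"].astype(bool)
    if drop_duplicates:
        keep &= ~df["is_duplicate"].astype(bool)
    return df.loc[keep].reset_index(drop=True)


def _merged_targets(panel: TargetPanel, flank_bp: int,
                    targets: str = "amplicons") -> dict[str, np.ndarray]:
    """Per-chromosome merged (start, end) arrays of target ± flank.

    ``targets="amplicons"`` uses the amplicon footprint (gene tiles plus the
    SNP amplicons — the "flanking regions" around each site); ``"sites"``
    uses the bare gene regions and point loci.
    """
    if targets == "amplicons":
        ivs_in = [iv for _, iv in panel.amplicons()] + list(panel.gene_regions)
    else:
        ivs_in = panel.target_intervals()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs_in:
        by_chrom.setdefault(iv.chrom, []).append(
            (max(0, iv.start - flank_bp), iv.end + flank_bp))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged


def _overlap_mask(df: pd.DataFrame, targets: dict[str, np.ndarray]) -> np.ndarray:
    """True where read [start, start+aligned_len) overlaps any target interval."""
    mask = np.zeros(len(df), dtype=bool)
    for chrom, ivs in targets.items():
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = df.loc[sel, "start"].to_numpy()
        ends = starts + df.loc[sel, "aligned_len"].to_numpy()
        # overlap with the merged, disjoint target list: find the first target
        # whose end is > read start, and check it begins before the read ends
        idx = np.searchsorted(ivs[:, 1], starts, side="right")
        hit = (idx < len(ivs)) & (ivs[np.minimum(idx, len(ivs) - 1), 0] < ends)
        mask[np.flatnonzero(sel)] = hit
    return mask


def route_reads(records, panel: TargetPanel, flank_bp: int = 0,
                targets: str = "amplicons") -> RoutedReads:
    """Partition filtered reads: ≥1 bp overlap with any panel target ± flank
    ⇒ on-target; everything else off-target."""
    df = _as_frame(records)
    if df.empty:
        empty = df.copy()
        return RoutedReads(empty, empty.copy(), pd.Series(dtype=int))
    mask = _overlap_mask(df, _merged_targets(panel, flank_bp, targets))
    on = df.loc[mask].reset_index(drop=True)
    off = df.loc[~mask].reset_index(drop=True)
    return RoutedReads(on, off, _count_amplicons(on, panel))


def _sorted_bounds(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted read start and end arrays, for overlap counts."""
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = starts + grp["aligned_len"].to_numpy()
        out[chrom] = (np.sort(starts), np.sort(ends))
    return out


def _overlap_count(bounds, iv) -> int:
    """Reads overlapping [iv.start, iv.end): total − (entirely left) −
    (entirely right), via binary search on the sorted bounds."""
    if iv.chrom not in bounds:
        return 0
    starts, ends = bounds[iv.chrom]
    n_start_before_end = int(np.searchsorted(starts, iv.end, side="left"))
    n_end_before_start = int(np.searchsorted(ends, iv.start, side="right"))
    return n_start_before_end - n_end_before_start


def _count_amplicons(on_target: pd.DataFrame, panel: TargetPanel) -> pd.Series:
    bounds = _sorted_bounds(on_target)
    return pd.Series({name: _overlap_count(bounds, iv)
                      for name, iv in panel.amplicons()}, dtype=int)


def qc_summary(routed: RoutedReads, read_len: int, genome_len: int,
               panel: TargetPanel) -> QcSummary:
    """Library QC: WGS/TES fractions, equivalent depths, amplicon on-target
    rate and uniformity (fraction of amplicons within tenfold of the mean)."""
    total = routed.n_total
    if total == 0:
        return QcSummary(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, warning="zero reads")
    frac_tes = len(routed.on_target) / total
    frac_wgs = len(routed.off_target) / total
    wgs_depth = len(routed.off_target) * read_len / genome_len

    # mean depth over panel point sites (SNPs + hotspots)
    on = routed.on_target
    bounds = _sorted_bounds(on)
    site_depths = [_overlap_count(bounds, site.locus)
                   for site in panel.all_sites]
    tes_depth = float(np.mean(site_depths)) if site_depths else 0.0

    counts = routed.per_amplicon_counts
    n_assigned = 0
    if not on.empty and len(counts):
        mask = _overlap_mask(on, _merged_targets_from_amplicons(panel))
        n_assigned = int(mask.sum())
    on_rate = n_assigned / len(on) if len(on) else 0.0
    if len(counts) and counts.mean() > 0:
        mean = counts.mean()
        uniformity = float(((counts >= mean / 10) & (counts <= mean * 10)).mean())
    else:
        uniformity = 0.0
    return QcSummary(total, frac_wgs, frac_tes, wgs_depth, tes_depth,
                     on_rate, uniformity)


def _merged_targets_from_amplicons(panel: TargetPanel) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, iv in panel.amplicons():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged
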