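"""Low-pass copy-number analysis.

The chromosomal arm works on *mappability windows*: each window holds a fixed
number of uniquely-mappable read start positions (default 100,000 simulated
50-mers), with consecutive windows sharing a fixed overlap (default 20,000
positions, i.e. a step of 80,000).  Read counts per window are GC-corrected
(GC-bin median scaling), normalised to the genome-wide mean (the normalized
depth ratio, NDR), merged ten windows at a time into copy-ratio bins, and
segmented by recursive binary segmentation.  Segments are classified with a
noise-adaptive (MAD-scaled) threshold, whole chromosomes with the 0.7–1.3
normal NDR range, and CNVs larger than 4 Mb are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AUTOSOMES
from .models import GenomicInterval


@dataclass
class WindowProfile:
    """Ordered windows with counts; wraps a DataFrame with columns
    chrom, start, end, pidx_start, pidx_end, n_mappable, gc, raw_count,
    corrected_count, ndr (the last three filled in by later stages)."""

    df: pd.DataFrame
    read_len: int = 50
    reads_per_window: int = 100_000
    overlap: int = 20_000

    @property
    def step(self) -> int:
        return self.reads_per_window - self.overlap

    def with_df(self, df: pd.DataFrame) -> "WindowProfile":
        return replace(self, df=df)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass
class CopyRatioProfile:
    """Copy-ratio bins (mean NDR of consecutive windows); df columns
    chrom, start, end, copy_ratio, n_windows."""

    df: pd.DataFrame
    bin_size_windows: int = 10
    n_dropped_partial: int = 0

    @property
    def cv(self) -> float:
        return copy_ratio_cv(self)


@dataclass
class Segment:
    interval: GenomicInterval
    mean_copy_ratio: float
    n_bins: int
    call: str = "unclassified"  # loss | gain | neutral | unclassified

    @property
    def size_bp(self) -> int:
        return self.interval.length


@dataclass
class ChromosomeCall:
    chrom: str
    chrom_ndr: float
    call: str  # monosomy | disomy | trisomy | other | expected


@dataclass
class CnvCall:
    interval: GenomicInterval
    direction: str  # deletion | duplication
    mean_copy_ratio: float

    @property
    def size_bp(self) -> int:
        return self.interval.length

    def karyotype_line(self) -> str:
        kind = "del" if self.direction == "deletion" else "dup"
        mb = self.size_bp / 1e6
        return (f"{kind}({self.interval.chrom}:"
                f"{self.interval.start / 1e6:.1f}-{self.interval.end / 1e6:.1f} Mb), "
                f"{mb:.1f} Mb")


# ---------------------------------------------------------------------------
# Window construction and counting
# ---------------------------------------------------------------------------

def build_windows(mappability: dict[str, int | np.ndarray], read_len: int = 50,
                  reads_per_window: int = 100_000,
                  overlap: int = 20_000) -> WindowProfile:
    """Build sliding mappability windows.

    ``mappability`` maps chromosome → either an integer length (every 50-mer
    start uniquely mappable, the synthetic-genome case) or a sorted array of
    uniquely-mappable start positions.  Windows hold ``reads_per_window``
    positions and advance by ``reads_per_window − overlap``; they never span
    chromosomes.  A trailing group of fewer than ``reads_per_window``
    positions is dropped, except that a chromosome with fewer mappable
    positions than one window becomes a single flagged whole-chromosome
    window.
    """
    if overlap >= reads_per_window:
        raise ValueError("overlap must be smaller than reads_per_window")
    step = reads_per_window - overlap
    rows = []
    for chrom, mask in mappability.items():
        if isinstance(mask, (int, np.integer)):
            length = int(mask)
            n_pos = max(0, length - read_len + 1)
            if n_pos == 0:
                continue
            if n_pos < reads_per_window:
                rows.append((chrom, 0, length, 0, n_pos, n_pos, 0.5, "small_chromosome"))
                continue
            k = 0
            while k * step + reads_per_window <= n_pos:
                p0 = k * step
                p1 = p0 + reads_per_window
                rows.append((chrom, p0, p1 - 1 + read_len, p0, p1,
                             reads_per_window, 0.5, ""))
                k += 1
        else:
            pos = np.asarray(mask)
            n_pos = len(pos)
            if n_pos == 0:
                continue
            if n_pos < reads_per_window:
                rows.append((chrom, int(pos[0]), int(pos[-1]) + read_len,
                             0, n_pos, n_pos, 0.5, "small_chromosome"))
                continue
            k = 0
            while k * step + reads_per_window <= n_pos:
                i0, i1 = k * step, k * step + reads_per_window
                rows.append((chrom, int(pos[i0]), int(pos[i1 - 1]) + read_len,
                             i0, i1, reads_per_window, 0.5, ""))
                k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "pidx_start",
                                     "pidx_end", "n_mappable", "gc", "flag"])
    return WindowProfile(df, read_len, reads_per_window, overlap)


def count_in_windows(off_target_reads, profile: WindowProfile,
                     mappability: dict[str, int | np.ndarray] | None = None
                     ) -> WindowProfile:
    """Assign each read (by start position) to every window containing it;
    overlapping windows both count a read in the shared region."""
    df = profile.df.copy()
    reads = off_target_reads
    if not isinstance(reads, pd.DataFrame):
        from .models import alignments_to_frame
        reads = alignments_to_frame(reads)
    counts = np.zeros(len(df), dtype=np.int64)
    for chrom, grp in df.groupby("chrom", sort=False):
        sel = reads["chrom"] == chrom
        starts = np.sort(reads.loc[sel, "start"].to_numpy())
        if mappability is not None and not isinstance(
                mappability.get(chrom, 0), (int, np.integer)):
            pos = np.asarray(mappability[chrom])
            pidx = np.searchsorted(pos, starts, side="right") - 1
            pidx = np.sort(np.clip(pidx, 0, len(pos) - 1))
        else:
            pidx = starts
        lo = np.searchsorted(pidx, grp["pidx_start"].to_numpy(), side="left")
        hi = np.searchsorted(pidx, grp["pidx_end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    df["raw_count"] = counts
    return profile.with_df(df)


# ---------------------------------------------------------------------------
# GC correction and normalization
# ---------------------------------------------------------------------------

def gc_correct(profile: WindowProfile, n_gc_bins: int = 50,
               min_windows_per_bin: int = 10) -> WindowProfile:
    """GC-bin median scaling: corrected = raw × global median / GC-bin median.

    The expected count at each window's GC is taken from the median-count
    curve over GC bins, linearly interpolated between populated bin centers
    (bins with fewer than ``min_windows_per_bin`` windows do not contribute
    a knot); with a single populated bin the correction degenerates to
    global median scaling.
    """
    df = profile.df.copy()
    raw = df["raw_count"].to_numpy(dtype=float)
    if raw.sum() == 0:
        raise ValueError("no coverage: all window counts are zero")
    gm = float(np.median(raw))
    gc = df["gc"].to_numpy(dtype=float)
    bins = np.clip((gc * n_gc_bins).astype(int), 0, n_gc_bins - 1)
    centers, medians = [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() >= min_windows_per_bin:
            centers.append(gc[sel].mean())
            medians.append(np.median(raw[sel]))
    factor = np.ones(len(df))
    if centers:
        expected = np.interp(gc, centers, medians)
        ok = expected > 0
        factor[ok] = gm / expected[ok]
    df["corrected_count"] = raw * factor
    return profile.with_df(df)


def compute_ndr(profile: WindowProfile) -> WindowProfile:
    """Normalized depth ratio: window count / genome-wide mean window count.
    Mean NDR is exactly 1 afterwards."""
    df = profile.df.copy()
    col = "corrected_count" if "corrected_count" in df else "raw_count"
    counts = df[col].to_numpy(dtype=float)
    mean = counts.mean()
    if mean == 0:
        raise ValueError("cannot normalize: mean window count is zero")
    df["ndr"] = counts / mean
    return profile.with_df(df)


def compute_copy_ratio(profile: WindowProfile, bin_size: int = 10,
                       decimate: bool = False) -> CopyRatioProfile:
    """Merge and average the NDR of each consecutive group of ``bin_size``
    windows per chromosome (trailing partial groups are dropped and counted).

    ``decimate=True`` first keeps every ⌈reads_per_window/step⌉-th window so
    bins are built from disjoint windows when windows overlap.
    """
    rows = []
    dropped = 0
    stride = math.ceil(profile.reads_per_window / profile.step) if decimate else 1
    for chrom, grp in profile.df.groupby("chrom", sort=False):
        grp = grp.iloc[::stride]
        n_full = len(grp) // bin_size
        dropped += int(len(grp) % bin_size > 0)
        for b in range(n_full):
            sub = grp.iloc[b * bin_size:(b + 1) * bin_size]
            rows.append((chrom, int(sub["start"].iloc[0]), int(sub["end"].iloc[-1]),
                         float(sub["ndr"].mean()), len(sub)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_ratio",
                                     "n_windows"])
    return CopyRatioProfile(df, bin_size, dropped)


def copy_ratio_cv(profile: CopyRatioProfile | np.ndarray) -> float:
    """Coefficient of variation of the copy ratio after excluding values
    outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]."""
    values = (profile.df["copy_ratio"].to_numpy()
              if isinstance(profile, CopyRatioProfile) else np.asarray(profile, float))
    if len(values) < 4:
        raise ValueError("need at least 4 copy-ratio bins for a CV")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    kept = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return float(np.std(kept, ddof=1) / np.mean(kept))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float, float] | None:
    """Best binary split of x maximizing the pooled two-sample t statistic.

    Returns (split index, |t|, p-value) or None when no admissible split.
    """
    n = len(x)
    if n < 2 * min_bins:
        return None
    s = np.cumsum(x)
    ss = np.cumsum(x * x)
    ks = np.arange(min_bins, n - min_bins + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = s[ks - 1]
    s2 = s[-1] - s1
    ss1 = ss[ks - 1]
    ss2 = ss[-1] - ss1
    m1 = s1 / n1
    m2 = s2 / n2
    rss = np.maximum(ss1 - n1 * m1 ** 2, 0.0) + np.maximum(ss2 - n2 * m2 ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = rss / (n - 2)
        t2 = (m1 - m2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
    # noiseless split: zero residual variance with distinct means
    exact = (sp2 <= 1e-24) & (np.abs(m1 - m2) > 1e-12)
    t2 = np.where(exact, np.inf, t2)
    t2 = np.nan_to_num(t2, nan=0.0)
    best = int(np.argmax(t2))
    tbest = math.sqrt(t2[best]) if np.isfinite(t2[best]) else math.inf
    if math.isinf(tbest):
        p = 0.0
    else:
        p = 2.0 * stats.t.sf(tbest, df=n - 2)
    return int(ks[best]), tbest, p


def _exact_decomposition(x: np.ndarray, min_bins: int) -> list[int] | None:
    """Exactly piecewise-constant data (every maximal constant run at least
    ``min_bins`` long) decomposes at the run boundaries with zero residual;
    any mean shift is then infinitely significant, so no test is needed.
    Returns None for data that is not noiseless-decomposable."""
    changes = np.flatnonzero(np.diff(x) != 0) + 1
    if len(changes) == 0:
        return []
    bounds = np.concatenate([[0], changes, [len(x)]])
    if (np.diff(bounds) >= min_bins).all():
        return [int(c) for c in changes]
    return None


def _binary_segment(x: np.ndarray, min_bins: int, alpha: float) -> list[int]:
    """Recursive binary segmentation; returns interior breakpoint indices."""
    n = len(x)
    exact = _exact_decomposition(x, min_bins)
    if exact is not None:
        return exact
    found = _best_split(x, min_bins)
    if found is None:
        return []
    k, _, p = found
    n_candidates = max(1, n - 2 * min_bins + 1)
    if p >= alpha / n_candidates:  # Bonferroni over candidate splits
        return []
    left = _binary_segment(x[:k], min_bins, alpha)
    right = _binary_segment(x[k:], min_bins, alpha)
    return left + [k] + [k + b for b in right]


def segment(profile: CopyRatioProfile, min_seg_bins: int = 3,
            alpha: float = 0.01) -> list[Segment]:
    """Per-chromosome recursive binary segmentation of the copy-ratio bins.
    Output segments tile each chromosome."""
    segments: list[Segment] = []
    for chrom, grp in profile.df.groupby("chrom", sort=False):
        x = grp["copy_ratio"].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        bps = sorted(_binary_segment(x, min_seg_bins, alpha))
        bounds = [0] + bps + [len(x)]
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            sub = grp.iloc[i0:i1]
            segments.append(Segment(
                GenomicInterval(chrom, int(sub["start"].iloc[0]),
                                int(sub["end"].iloc[-1])),
                float(sub["copy_ratio"].mean()), i1 - i0))
    return segments


def refine_segment_boundaries(segments: list[Segment],
                              profile: WindowProfile,
                              halo_windows: int = 10) -> list[Segment]:
    """Sharpen segment boundaries to window resolution.

    Copy-ratio bins quantize breakpoints to ~0.8 Mb; for each boundary
    between adjacent segments the window-level NDR within ``halo_windows``
    windows on either side is re-split at the position minimizing the
    two-mean residual sum of squares, and both segments are snapped to that
    window edge.  Tiling and bin counts are preserved.
    """
    df = profile.df
    out = [replace(s) for s in segments]
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(out):
        by_chrom.setdefault(s.interval.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        grp = df[df["chrom"] == chrom]
        starts = grp["start"].to_numpy()
        ndr = grp["ndr"].to_numpy(dtype=float)
        for a, b in zip(idxs[:-1], idxs[1:]):
            if out[a].mean_copy_ratio == out[b].mean_copy_ratio:
                continue
            boundary = out[a].interval.end
            centre = int(np.searchsorted(starts, boundary, side="left"))
            lo = max(0, centre - halo_windows)
            hi = min(len(ndr), centre + halo_windows)
            x = ndr[lo:hi]
            if len(x) < 2:
                continue
            s_cum = np.cumsum(x)
            total = s_cum[-1]
            ks = np.arange(1, len(x))
            rss = -(s_cum[ks - 1] ** 2 / ks
                    + (total - s_cum[ks - 1]) ** 2 / (len(x) - ks))
            k = int(ks[np.argmin(rss)])
            new_boundary = int(starts[lo + k]) if lo + k < len(starts) else boundary
            if (new_boundary > out[a].interval.start
                    and new_boundary < out[b].interval.end):
                out[a] = replace(out[a], interval=GenomicInterval(
                    chrom, out[a].interval.start, new_boundary))
                out[b] = replace(out[b], interval=GenomicInterval(
                    chrom, new_boundary, out[b].interval.end))
    return out


def dynamic_threshold_filter(segments: list[Segment],
                             profile: CopyRatioProfile, k: float = 3.0,
                             floor: float = 0.3) -> list[Segment]:
    """Noise-adaptive segment classification.

    The per-sample noise scale σ̂ = 1.4826·MAD of the copy-ratio bins; a
    segment of n bins is a loss (gain) when its mean copy ratio is below
    1 − max(floor, k·σ̂/√n) (above 1 + the same).  The floor keeps
    sub-mosaic shifts from being called.
    """
    x = profile.df["copy_ratio"].to_numpy(dtype=float)
    sigma = 1.4826 * float(np.median(np.abs(x - np.median(x)))) if len(x) else 0.0
    out = []
    for seg in segments:
        thr = max(floor, k * sigma / math.sqrt(max(seg.n_bins, 1)))
        if seg.mean_copy_ratio < 1.0 - thr:
            call = "loss"
        elif seg.mean_copy_ratio > 1.0 + thr:
            call = "gain"
        else:
            call = "neutral"
        out.append(replace(seg, call=call))
    return out


# ---------------------------------------------------------------------------
# Chromosome-level and CNV calls
# ---------------------------------------------------------------------------

def call_chromosomes(profile: WindowProfile,
                     normal_range: tuple[float, float] = (0.7, 1.3),
                     sex: str = "auto") -> list[ChromosomeCall]:
    """Whole-chromosome aneuploidy calls from the length-weighted mean NDR.

    Autosomes: NDR below the normal range ⇒ monosomy, above ⇒ trisomy,
    inside ⇒ disomy (near-zero ⇒ other).  Sex chromosomes are judged
    relative to the copy number expected for the inferred sex (chrY
    coverage test) and labelled "expected" when concordant.
    """
    df = profile.df
    lo, hi = normal_range
    weighted = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        w = (grp["end"] - grp["start"]).to_numpy(dtype=float)
        weighted[chrom] = float(np.average(grp["ndr"].to_numpy(), weights=w))
    if sex == "auto":
        y_ndr = weighted.get("chrY", 0.0)
        sex = "male" if y_ndr > 0.25 else "female"
    calls = []
    for chrom, ndr in weighted.items():
        if chrom in AUTOSOMES:
            if ndr < 0.25:
                call = "other"
            elif ndr < lo:
                call = "monosomy"
            elif ndr > hi:
                call = "trisomy"
            else:
                call = "disomy"
        else:
            expected = {"chrX": 1.0 if sex == "female" else 0.5,
                        "chrY": 0.0 if sex == "female" else 0.5}[chrom]
            if expected == 0.0:
                call = "expected" if ndr < 0.25 else "other"
            else:
                ratio = ndr / expected
                call = ("expected" if lo <= ratio <= hi
                        else "loss" if ratio < lo else "gain")
        calls.append(ChromosomeCall(chrom, ndr, call))
    return calls


def report_cnvs(segments: list[Segment],
                min_report_size: int = 4_000_000) -> list[CnvCall]:
    """Merge adjacent same-direction non-neutral segments and report those
    larger than ``min_report_size``."""
    merged: list[Segment] = []
    for seg in segments:
        if seg.call not in ("loss", "gain"):
            merged.append(seg)
            continue
        prev = merged[-1] if merged else None
        if (prev is not None and prev.call == seg.call
                and prev.interval.chrom == seg.interval.chrom
                and prev.interval.end >= seg.interval.start):
            total_bins = prev.n_bins + seg.n_bins
            mean = (prev.mean_copy_ratio * prev.n_bins
                    + seg.mean_copy_ratio * seg.n_bins) / total_bins
            merged[-1] = Segment(
                GenomicInterval(prev.interval.chrom, prev.interval.start,
                                seg.interval.end), mean, total_bins, seg.call)
        else:
            merged.append(seg)
    out = []
    for seg in merged:
        if seg.call in ("loss", "gain") and seg.size_bp > min_report_size:
            out.append(CnvCall(seg.interval,
                               "deletion" if seg.call == "loss" else "duplication",
                               seg.mean_copy_ratio))
    return out


def call_sample(profile_with_counts: WindowProfile, bin_size: int = 10,
                min_seg_bins: int = 3, alpha: float = 0.01,
                threshold_k: float = 3.0, threshold_floor: float = 0.3,
                min_report_size: int = 4_000_000,
                normal_range: tuple[float, float] = (0.7, 1.3)) -> dict:
    """Convenience driver: GC correction → NDR → copy ratio → segmentation →
    dynamic-threshold filtering → chromosome and CNV calls."""
    prof = gc_correct(profile_with_counts)
    prof = compute_ndr(prof)
    bins = compute_copy_ratio(prof, bin_size=bin_size)
    segs = segment(bins, min_seg_bins=min_seg_bins, alpha=alpha)
    segs = refine_segment_boundaries(segs, prof, halo_windows=bin_size)
    segs = dynamic_threshold_filter(segs, bins, k=threshold_k, floor=threshold_floor)
    chrom_calls = call_chromosomes(prof, normal_range=normal_range)
    cnvs = report_cnvs(segs, min_report_size=min_report_size)
    return {"profile": prof, "bins": bins, "segments": segs,
            "chromosome_calls": chrom_calls, "cnvs": cnvs}
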