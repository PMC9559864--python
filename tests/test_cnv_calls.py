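"""Segmentation, dynamic-threshold classification, chromosome and CNV calls."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tags_pgt.cnv import (
    CopyRatioProfile,
    Segment,
    WindowProfile,
    call_chromosomes,
    call_sample,
    dynamic_threshold_filter,
    report_cnvs,
    segment,
)
from tags_pgt.genome import AUTOSOMES, scaled_genome
from tags_pgt.models import GenomicInterval
from tags_pgt.simulate import SimConfig, simulate_window_counts
from tags_pgt.cnv import build_windows


def bins_profile(values, chrom="chr1", bin_bp=1_000_000):
    n = len(values)
    df = pd.DataFrame({
        "chrom": [chrom] * n,
        "start": np.arange(n) * bin_bp,
        "end": (np.arange(n) + 1) * bin_bp,
        "copy_ratio": np.asarray(values, dtype=float),
        "n_windows": 10,
    })
    return CopyRatioProfile(df, 10)


def exhaustive_changepoints(x, min_len=3, tol=1e-12):
    """Oracle: the smallest breakpoint set achieving (near-)zero residual sum
    of squares, via exhaustive least-squares dynamic programming over all
    admissible partitions (segments of at least ``min_len`` bins)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_rss(a, b):
        if b - a < min_len:
            return np.inf
        m = (s[b] - s[a]) / (b - a)
        return max(ss[b] - ss[a] - (b - a) * m * m, 0.0)

    max_segments = n // min_len
    # best[k][i]: minimal RSS of x[:i] split into exactly k segments
    best = {1: {i: seg_rss(0, i) for i in range(n + 1)}}
    back: dict[int, dict[int, int]] = {}
    for k in range(1, max_segments + 1):
        if k > 1:
            best[k] = {}
            back[k] = {}
            for i in range(n + 1):
                options = [(best[k - 1][j] + seg_rss(j, i), j)
                           for j in range(n + 1)]
                val, arg = min(options)
                best[k][i] = val
                back[k][i] = arg
        if best[k][n] <= tol:
            bps = []
            i = n
            for kk in range(k, 1, -1):
                i = back[kk][i]
                bps.append(i)
            return sorted(bps)
    return []


def observed_breakpoints(segments, bin_bp=1_000_000):
    bounds = sorted({s.interval.start for s in segments})
    return [b // bin_bp for b in bounds if b > 0]


class TestSegmentation:
    @pytest.mark.parametrize("pattern", [
        [(50, 1.0), (20, 0.5), (30, 1.0)],
        [(10, 1.0), (10, 1.5)],
        [(5, 0.5), (5, 1.0), (5, 1.5), (5, 1.0)],
        [(40, 1.0)],
        [(3, 1.0), (3, 0.2), (3, 1.0)],
    ])
    def test_matches_exhaustive_oracle_on_noiseless_profiles(self, pattern):
        x = np.concatenate([np.full(n, v) for n, v in pattern])
        segs = segment(bins_profile(x))
        assert observed_breakpoints(segs) == exhaustive_changepoints(x)
        assert sum(s.n_bins for s in segs) == len(x)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(3, 12),
                              st.sampled_from([0.3, 0.5, 1.0, 1.5, 2.0])),
                    min_size=1, max_size=5))
    def test_oracle_equivalence_property(self, pieces):
        # merge adjacent pieces with equal level so changepoints are real
        levels = []
        for n, v in pieces:
            if levels and levels[-1][1] == v:
                levels[-1][0] += n
            else:
                levels.append([n, v])
        x = np.concatenate([np.full(n, v) for n, v in levels])
        assert len(x) <= 100
        segs = segment(bins_profile(x))
        assert observed_breakpoints(segs) == exhaustive_changepoints(x)

    def test_constant_profile_single_segment(self):
        segs = segment(bins_profile(np.full(50, 1.0)))
        assert len(segs) == 1
        assert segs[0].n_bins == 50

    def test_noisy_deletion_recovered(self, rng):
        x = rng.normal(1.0, 0.05, size=100)
        x[40:60] = rng.normal(0.5, 0.05, size=20)
        segs = segment(bins_profile(x))
        segs = dynamic_threshold_filter(segs, bins_profile(x))
        losses = [s for s in segs if s.call == "loss"]
        assert len(losses) == 1
        assert abs(losses[0].interval.start // 1_000_000 - 40) <= 1
        assert abs(losses[0].interval.end // 1_000_000 - 60) <= 1

    def test_segments_tile_each_chromosome(self, rng):
        x = np.concatenate([np.full(30, 1.0), np.full(10, 1.5)])
        x += rng.normal(0, 0.02, size=len(x))
        segs = segment(bins_profile(x))
        starts = [s.interval.start for s in segs]
        ends = [s.interval.end for s in segs]
        assert starts[0] == 0
        assert ends[-1] == len(x) * 1_000_000
        assert starts[1:] == ends[:-1]


class TestDynamicThreshold:
    def test_small_shift_in_quiet_sample_is_neutral(self):
        prof = bins_profile(np.full(100, 1.0))
        segs = [Segment(GenomicInterval("chr1", 0, 10_000_000), 1.02, 10)]
        out = dynamic_threshold_filter(segs, prof)
        assert out[0].call == "neutral"

    def test_het_deletion_called_loss(self, rng):
        prof = bins_profile(np.clip(rng.normal(1, 0.05, 200), 0.01, None))
        segs = [Segment(GenomicInterval("chr1", 0, 20_000_000), 0.5, 20)]
        out = dynamic_threshold_filter(segs, prof)
        assert out[0].call == "loss"

    def test_threshold_adapts_to_noise(self, rng):
        """A 0.8-level segment is loss in a quiet sample but neutral in a
        very noisy one (σ̂ ≈ 0.4)."""
        quiet = bins_profile(rng.normal(1, 0.02, 300))
        noisy = bins_profile(rng.normal(1, 0.4, 300))
        seg = [Segment(GenomicInterval("chr1", 0, 5_000_000), 0.55, 5)]
        assert dynamic_threshold_filter(seg, quiet)[0].call == "loss"
        assert dynamic_threshold_filter(seg, noisy)[0].call == "neutral"


class TestChromosomeCalls:
    def window_profile(self, ndr_by_chrom):
        rows = []
        for chrom, ndrs in ndr_by_chrom.items():
            for i, v in enumerate(ndrs):
                rows.append((chrom, i * 100_000, (i + 1) * 100_000, 0, 0,
                             100_000, 0.5, "", 100, 100.0, v))
        df = pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "pidx_start", "pidx_end", "n_mappable",
            "gc", "flag", "raw_count", "corrected_count", "ndr"])
        return WindowProfile(df)

    @pytest.mark.parametrize("ndr,expected", [
        (0.52, "monosomy"), (1.0, "disomy"), (1.48, "trisomy"),
        (0.70, "disomy"), (1.30, "disomy"),
    ])
    def test_normal_range_rule(self, ndr, expected):
        prof = self.window_profile({"chr13": np.full(20, ndr),
                                    "chr1": np.full(20, 1.0)})
        calls = {c.chrom: c.call for c in call_chromosomes(prof)}
        assert calls["chr13"] == expected

    def test_length_weighting(self):
        prof = self.window_profile({"chr1": [1.0] * 10})
        df = prof.df.copy()
        # make one window 10× longer with NDR 2.0: weighted mean pulled up
        df.loc[0, "end"] = df.loc[0, "start"] + 1_000_000
        df.loc[0, "ndr"] = 2.0
        calls = call_chromosomes(prof.with_df(df))
        expected = (2.0 * 1_000_000 + 9 * 100_000) / (1_000_000 + 9 * 100_000)
        assert calls[0].chrom_ndr == pytest.approx(expected)

    def test_female_chry_is_expected_absent(self):
        prof = self.window_profile({"chr1": np.full(20, 1.0),
                                    "chrX": np.full(20, 1.0),
                                    "chrY": np.full(5, 0.01)})
        calls = {c.chrom: c.call for c in call_chromosomes(prof)}
        assert calls["chrY"] == "expected"
        assert calls["chrX"] == "expected"


class TestReportCnvs:
    def seg(self, chrom, start_mb, end_mb, ratio, call, n_bins=10):
        return Segment(GenomicInterval(chrom, int(start_mb * 1e6),
                                       int(end_mb * 1e6)), ratio, n_bins, call)

    def test_large_loss_reported_small_suppressed(self):
        segs = [self.seg("chr2", 0, 19.36, 0.5, "loss"),
                self.seg("chr3", 0, 3.5, 0.5, "loss")]
        cnvs = report_cnvs(segs)
        assert len(cnvs) == 1
        assert cnvs[0].direction == "deletion"
        assert round(cnvs[0].size_bp / 1e6, 1) == 19.4

    def test_adjacent_same_direction_merged(self):
        segs = [self.seg("chr5", 0, 3, 0.5, "loss"),
                self.seg("chr5", 3, 6, 0.45, "loss")]
        cnvs = report_cnvs(segs)
        assert len(cnvs) == 1
        assert cnvs[0].size_bp == 6_000_000

    def test_karyotype_line_format(self):
        cnvs = report_cnvs([self.seg("chr2", 174.6, 194.0, 0.5, "loss")])
        assert cnvs[0].karyotype_line().startswith("del(chr2:")
        assert "19.4 Mb" in cnvs[0].karyotype_line()


class TestBoundaryRefinement:
    def test_refined_boundary_snaps_to_window_level_changepoint(self):
        """The bin-quantized breakpoint moves to the window where the NDR
        level actually changes."""
        from tags_pgt.cnv import WindowProfile, refine_segment_boundaries
        import pandas as pd
        n = 60
        true_change = 23  # window index, mid-bin
        df = pd.DataFrame({
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "n_mappable": 100_000,
            "gc": 0.5,
            "ndr": np.where(np.arange(n) < true_change, 1.0, 0.5),
        })
        prof = WindowProfile(df, 50, 100_000, 0)
        segs = [
            Segment(GenomicInterval("chr1", 0, 20 * 100_000), 1.0, 2),
            Segment(GenomicInterval("chr1", 20 * 100_000, n * 100_000), 0.55, 4),
        ]
        refined = refine_segment_boundaries(segs, prof, halo_windows=10)
        assert refined[0].interval.end == true_change * 100_000
        assert refined[1].interval.start == true_change * 100_000

    def test_constant_profile_untouched(self):
        from tags_pgt.cnv import WindowProfile, refine_segment_boundaries
        import pandas as pd
        df = pd.DataFrame({
            "chrom": ["chr1"] * 20, "start": np.arange(20) * 100_000,
            "end": (np.arange(20) + 1) * 100_000, "n_mappable": 100_000,
            "gc": 0.5, "ndr": 1.0})
        prof = WindowProfile(df, 50, 100_000, 0)
        segs = [Segment(GenomicInterval("chr1", 0, 2_000_000), 1.0, 2)]
        assert refine_segment_boundaries(segs, prof) == segs


class TestPlantedEvents:
    def test_planted_deletions_recovered_with_tight_boundaries(self):
        """≥8 Mb heterozygous deletions at 0.3× are recovered with boundary
        error ≤1 copy-ratio bin and correct direction across replicates."""
        sizes = {"chr2": scaled_genome(1.0)["chr2"]}
        windows = build_windows(sizes)
        bin_bp = 800_000 * 10
        dele = GenomicInterval("chr2", 60_000_000, 72_000_000)  # 12 Mb
        for seed in range(5):
            cfg = SimConfig(seed=seed, cnv_events=[(dele, 1)])
            counted = simulate_window_counts(windows, cfg)
            res = call_sample(counted)
            dels = [c for c in res["cnvs"] if c.direction == "deletion"]
            assert len(dels) == 1
            assert abs(dels[0].interval.start - dele.start) <= bin_bp
            assert abs(dels[0].interval.end - dele.end) <= bin_bp

    def test_euploid_specificity(self):
        """Euploid female samples: no reported CNVs and 22 autosomal disomy
        calls in ≥95% of seeds."""
        sizes = scaled_genome(0.25, include_y=False)
        windows = build_windows(sizes)
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=1000 + seed)
            counted = simulate_window_counts(windows, cfg)
            res = call_sample(counted)
            disomies = sum(c.call == "disomy" for c in res["chromosome_calls"]
                           if c.chrom in AUTOSOMES)
            if not res["cnvs"] and disomies == 22:
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_gc_bias_invariance_of_calls(self):
        """Calls agree between GC-biased and unbiased simulations of the
        same karyotype after GC correction."""
        sizes = {"chr2": scaled_genome(0.5)["chr2"]}
        windows = build_windows(sizes)
        dele = GenomicInterval("chr2", 40_000_000, 55_000_000)
        flat = SimConfig(seed=5, cnv_events=[(dele, 1)])
        biased = SimConfig(seed=5, cnv_events=[(dele, 1)],
                           gc_bias_coefficients=(1.0, 2.0))
        res_flat = call_sample(simulate_window_counts(windows, flat))
        res_biased = call_sample(simulate_window_counts(windows, biased))
        two_bins = 2 * 10 * 80_000  # copy-ratio bin ≈ 0.8 Mb
        for res in (res_flat, res_biased):
            dels = [c for c in res["cnvs"] if c.direction == "deletion"]
            assert len(dels) == 1
            assert abs(dels[0].size_bp - dele.length) <= two_bins
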