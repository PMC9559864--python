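import numpy as np
import pytest

from tags_pgt.io import builtin_panel
from tags_pgt.models import GenomicInterval, HotspotLocus, SnpSite, TargetPanel


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_snp_panel(n_snps: int, chrom: str = "chr11", start: int = 4_500_000,
                   spacing: int = 100, maf: float = 0.4,
                   with_hotspots: bool = True) -> TargetPanel:
    """A synthetic panel with evenly spaced SNPs, for scaling tests."""
    snps = [SnpSite(f"s{i:05d}", GenomicInterval(chrom, start + i * spacing,
                                                 start + i * spacing + 1),
                    "A", "G", maf) for i in range(n_snps)]
    hotspots = []
    gene_mid = start + n_snps * spacing + 10_000
    if with_hotspots:
        hotspots = [
            HotspotLocus("hotA", GenomicInterval(chrom, gene_mid, gene_mid + 1),
                         "C", "T"),
            HotspotLocus("hotB", GenomicInterval(chrom, gene_mid + 100,
                                                 gene_mid + 101), "G", "A"),
        ]
    gene = [GenomicInterval(chrom, gene_mid - 1000, gene_mid + 2000)]
    return TargetPanel(gene, snps, hotspots)


@pytest.fixture()
def toy_sam(tmp_path):
    """A 10-record single-end toy SAM on hg19-named contigs."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chr1\tLN:249250621",
        "@SQ\tSN:chr11\tLN:135006516",
    ]
    # (name, flag, chrom, pos1, mapq, cigar)
    recs = [
        ("r1", 0, "chr1", 100, 60, "50M"),
        ("r2", 0, "chr1", 200, 60, "50M"),
        ("r3", 16, "chr1", 300, 60, "50M"),
        ("r4", 0, "chr11", 5_246_700, 60, "50M"),
        ("r5", 0, "chr11", 5_247_000, 0, "50M"),      # MAPQ 0 → non-unique
        ("r6", 1024, "chr1", 400, 60, "50M"),          # duplicate
        ("r7", 0, "chr1", 500, 60, "25M"),
        ("r8", 0, "chr11", 5_248_000, 60, "50M"),
        ("r9", 0, "chr1", 700, 60, "50M"),
        ("r10", 0, "chr1", 800, 60, "50M"),
    ]
    for name, flag, chrom, pos, mapq, cigar in recs:
        seq_len = int(cigar[:-1])
        lines.append("\t".join([
            name, str(flag), chrom, str(pos), str(mapq), cigar, "*", "0", "0",
            "A" * seq_len, "I" * seq_len]))
    path = tmp_path / "toy.sam"
    path.write_text("\n".join(lines) + "\n")
    return path
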