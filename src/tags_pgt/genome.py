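"""Reference-genome naming and sizes (hg19 / GRCh37).

Internally everything is 0-based half-open; chromosome naming follows the
UCSC ``chr``-prefixed convention.  A *scaled* genome — same chromosome names,
lengths multiplied by a constant — is used by the simulator so tests run in
seconds; coordinates scale linearly.
"""

from __future__ import annotations

HG19_SIZES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

VALID_CHROMS: frozenset[str] = frozenset(HG19_SIZES) | {"chrM"}


def scaled_genome(scale: float = 1.0, chroms: tuple[str, ...] | None = None,
                  include_y: bool = True) -> dict[str, int]:
    """Chromosome → length map, optionally scaled down and/or restricted.

    Parameters
    ----------
    scale
        Multiplier on the hg19 lengths (e.g. ``0.1`` for a 1/10 miniature).
    chroms
        Explicit chromosome subset; default all autosomes + X (+ Y).
    include_y
        Drop chrY (female genome) when False.
    """
    if chroms is None:
        chroms = AUTOSOMES + (("chrX", "chrY") if include_y else ("chrX",))
    return {c: max(1, int(HG19_SIZES[c] * scale)) for c in chroms}


def genome_length(sizes: dict[str, int]) -> int:
    return sum(sizes.values())
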