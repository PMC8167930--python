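"""Model genome used by the simulators.

A 22-autosome genome with hg19-like chromosome lengths is embedded as a
constant so that breakpoint simulation needs no reference download.
Positions are 1-based throughout the package.
"""

from __future__ import annotations

import numpy as np

AUTOSOME_LENGTHS_BP: dict[str, int] = {
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
}

CHROMOSOMES: tuple[str, ...] = tuple(AUTOSOME_LENGTHS_BP)

_LENGTHS = np.array(list(AUTOSOME_LENGTHS_BP.values()), dtype=float)
CHROMOSOME_WEIGHTS: np.ndarray = _LENGTHS / _LENGTHS.sum()
GENOME_LENGTH_BP: int = int(_LENGTHS.sum())
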