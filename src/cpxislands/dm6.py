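"""Published dm6 (Drosophila melanogaster Release 6) island statistics.

Reference per-chromosome tallies from a whole-genome CpX island scan of
assembly GCF_000001215.4 with the default detection parameters (window
500 bp, CX ≥ 0.55, O/E ≥ 0.65, merge gap 100 bp).  These are inputs for
arithmetic cross-checks — recomputing frequency, coverage and totals
from counts — not outputs of this package; reproducing the counts
themselves requires downloading the assembly and running ``detect``.
"""

from __future__ import annotations

CHROM_LENGTHS: dict[str, int] = {
    "X": 23_542_271,
    "2L": 23_513_712,
    "2R": 25_286_936,
    "3L": 28_110_227,
    "3R": 32_079_331,
    "4": 1_348_131,
    "Y": 3_667_352,
    "MT": 19_524,
}

# Per-chromosome island counts, keyed by the second nucleotide X.
ISLAND_COUNTS: dict[str, dict[str, int]] = {
    "G": {"X": 3066, "2L": 2269, "2R": 3179, "3L": 2784, "3R": 3701,
          "4": 19, "Y": 162, "MT": 0},
    "A": {"X": 7316, "2L": 7190, "2R": 7358, "3L": 8391, "3R": 9457,
          "4": 308, "Y": 681, "MT": 3},
    "T": {"X": 7751, "2L": 7420, "2R": 7270, "3L": 8637, "3R": 9814,
          "4": 365, "Y": 781, "MT": 7},
}

# Per-chromosome summed island lengths in bp, keyed by X.
ISLAND_SUM_BP: dict[str, dict[str, int]] = {
    "G": {"X": 3_407_151, "2L": 2_105_771, "2R": 2_906_926, "3L": 2_589_377,
          "3R": 3_542_220, "4": 17_907, "Y": 206_793, "MT": 0},
    "A": {"X": 7_028_647, "2L": 6_520_015, "2R": 7_384_236, "3L": 8_115_587,
          "3R": 9_315_582, "4": 265_069, "Y": 1_302_828, "MT": 1962},
    "T": {"X": 7_121_642, "2L": 6_516_279, "2R": 6_904_591, "3L": 8_265_926,
          "3R": 9_023_611, "4": 313_929, "Y": 995_309, "MT": 5765},
}

# Reported genome-wide totals and medians for the same scan.
TOTAL_COUNTS: dict[str, int] = {"G": 15_180, "A": 40_704, "T": 42_045, "C": 0}
MEDIAN_LENGTH_BP: dict[str, int] = {"G": 733, "A": 692, "T": 694}

# Transposable-element overlap tally for the most island-associated
# family: 144 roo loci, 388 (locus, CpA island) overlapping pairs.
ROO_TOTAL = 144
ROO_PAIRS = 388
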