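"""Overlap reporting between islands and annotation features.

Counts (feature, island) pairs per feature type — a transposable-element
locus spanning several islands contributes several pairs, so per-type
percentages can exceed 100 — and provides a permutation null in which
islands are relocated uniformly at random on their own chromosomes.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CpXIsland

__all__ = [
    "GenomicFeature",
    "OverlapReportRow",
    "EnrichmentResult",
    "overlap_report",
    "filter_enriched",
    "permutation_enrichment",
]


@dataclass(frozen=True)
class GenomicFeature:
    """An annotated interval (0-based half-open) with a type label."""

    seq_id: str
    start: int
    end: int
    type_label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if not self.type_label:
            raise ValueError("type_label must be non-empty")


@dataclass(frozen=True)
class OverlapReportRow:
    """Per-type overlap tally.

    ``overlapping_pairs`` counts (feature, island) pairs sharing at least
    1 bp; ``pct`` = pairs / total features of the type × 100, rounded
    half away from zero to an integer, and may exceed 100.
    """

    type_label: str
    total_count: int
    overlapping_pairs: int

    @property
    def pct(self) -> int:
        return overlap_percentage(self.overlapping_pairs, self.total_count)


def overlap_percentage(pairs: int, total: int) -> int:
    """pairs/total as an integer percentage, rounded half away from zero."""
    return int(math.floor(pairs / total * 100 + 0.5))


class _IntervalIndex:
    """Sorted start/end arrays per chromosome for O(log n) overlap counts."""

    def __init__(self, intervals: Sequence[tuple[str, int, int]]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, start, end in intervals:
            self._starts.setdefault(chrom, []).append(start)
            self._ends.setdefault(chrom, []).append(end)
        for chrom in self._starts:
            self._starts[chrom].sort()
            self._ends[chrom].sort()

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        # An interval overlaps [start, end) iff its start < end and its
        # end > start; the two complements are disjoint, so counting via
        # independently sorted starts and ends is exact.
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        return len(starts) - (len(starts) - bisect_left(starts, end)) - bisect_right(ends, start)


def overlap_report(islands: Sequence[CpXIsland],
                   features: Sequence[GenomicFeature]) -> list[OverlapReportRow]:
    """Per-feature-type overlap counts against a set of islands.

    Rows are ordered by descending percentage, then by type label.
    Empty inputs yield an empty report.
    """
    if not features:
        return []
    index = _IntervalIndex([(i.seq_id, i.start, i.end) for i in islands])
    totals: dict[str, int] = {}
    pairs: dict[str, int] = {}
    for feat in features:
        totals[feat.type_label] = totals.get(feat.type_label, 0) + 1
        n = index.count_overlapping(feat.seq_id, feat.start, feat.end)
        pairs[feat.type_label] = pairs.get(feat.type_label, 0) + n
    rows = [
        OverlapReportRow(type_label=label, total_count=totals[label],
                         overlapping_pairs=pairs[label])
        for label in totals
    ]
    rows.sort(key=lambda r: (-r.pct, r.type_label))
    return rows


def filter_enriched(report: Sequence[OverlapReportRow], min_pct: int = 75,
                    min_total: int = 10) -> list[OverlapReportRow]:
    """Rows with pct ≥ min_pct and total_count ≥ min_total (both inclusive).

    The defaults mirror the usual screen for island-associated feature
    types: at least three quarters of the loci of a type overlapping an
    island, with at least 10 loci so that small families do not surface
    by chance.
    """
    return [r for r in report if r.pct >= min_pct and r.total_count >= min_total]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs permuted island/feature intersection.

    ``observed_bp`` is the summed intersection of every island with the
    union of the features.  ``fold`` is observed_bp over the mean
    permuted intersection;
    ``fold_defined`` is False when the permuted mean is 0 (fold reported
    as inf for positive observed overlap, 0 otherwise).  ``p_emp`` is the
    add-one empirical p-value (1 + #{permutations ≥ observed}) /
    (n_perm + 1).
    """

    observed_bp: int
    mean_permuted_bp: float
    fold: float
    fold_defined: bool
    p_emp: float
    n_perm: int
    rng_seed: int


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class _CoverageIndex:
    """bp covered by a fixed union of intervals, queryable per span."""

    def __init__(self, intervals: list[tuple[int, int]]):
        merged = _union(intervals)
        self._starts = np.array([s for s, _ in merged], dtype=np.int64)
        self._ends = np.array([e for _, e in merged], dtype=np.int64)
        self._cum = np.concatenate(([0], np.cumsum(self._ends - self._starts)))

    def _covered_before(self, x: np.ndarray) -> np.ndarray:
        """Covered bp in [0, x) for each x, vectorized."""
        i = np.searchsorted(self._starts, x, side="right") - 1
        safe = np.maximum(i, 0)
        partial = np.clip(x - self._starts[safe], 0, self._ends[safe] - self._starts[safe])
        return np.where(i >= 0, self._cum[safe] + partial, 0)

    def overlap_bp(self, starts: np.ndarray, ends: np.ndarray) -> int:
        if len(self._starts) == 0 or len(starts) == 0:
            return 0
        return int((self._covered_before(ends) - self._covered_before(starts)).sum())


def permutation_enrichment(islands: Sequence[CpXIsland],
                           features: Sequence[GenomicFeature],
                           chrom_sizes: dict[str, int],
                           n_perm: int = 100,
                           rng_seed: int = 0) -> EnrichmentResult:
    """Compare observed island/feature overlap with a shuffled-island null.

    Each permutation relocates every island uniformly at random on its
    own chromosome (start ~ uniform over [0, chrom_len − island_len]),
    preserving lengths and chromosome assignment; shuffled islands may
    overlap each other.  Overlap is measured as the summed intersection
    of each island with the union of the features — identically for the
    observed and every permuted configuration, which makes each island's
    contribution exchangeable under the null.  Deterministic given
    ``rng_seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for isl in islands:
        if isl.seq_id not in chrom_sizes:
            raise ValueError(f"island on unknown sequence {isl.seq_id!r}")
        if isl.length > chrom_sizes[isl.seq_id]:
            raise ValueError(
                f"island [{isl.start},{isl.end}) longer than sequence {isl.seq_id!r}"
            )
    feats_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        feats_by_chrom.setdefault(f.seq_id, []).append((f.start, f.end))
    coverage = {chrom: _CoverageIndex(iv) for chrom, iv in feats_by_chrom.items()}

    isl_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {i.seq_id for i in islands}:
        starts = np.array([i.start for i in islands if i.seq_id == chrom], dtype=np.int64)
        lens = np.array([i.length for i in islands if i.seq_id == chrom], dtype=np.int64)
        isl_by_chrom[chrom] = (starts, lens)

    def total_overlap(placements: dict[str, np.ndarray]) -> int:
        return sum(
            coverage[chrom].overlap_bp(starts, starts + isl_by_chrom[chrom][1])
            for chrom, starts in placements.items()
            if chrom in coverage
        )

    observed = total_overlap({c: s for c, (s, _) in isl_by_chrom.items()})

    rng = np.random.default_rng(rng_seed)
    max_start = {
        chrom: chrom_sizes[chrom] - lens
        for chrom, (_, lens) in isl_by_chrom.items()
    }
    permuted = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        placed = {
            chrom: rng.integers(0, bounds + 1)
            for chrom, bounds in max_start.items()
        }
        permuted[p] = total_overlap(placed)

    mean_perm = float(permuted.mean()) if n_perm else 0.0
    if mean_perm > 0:
        fold, fold_defined = observed / mean_perm, True
    else:
        fold, fold_defined = (math.inf if observed > 0 else 0.0), False
    p_emp = (1 + int((permuted >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed_bp=observed, mean_permuted_bp=mean_perm, fold=fold,
        fold_defined=fold_defined, p_emp=p_emp, n_perm=n_perm, rng_seed=rng_seed,
    )
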