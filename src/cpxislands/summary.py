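"""Per-chromosome island statistics, long-island subsets, and shores."""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .core import CpXIsland

__all__ = [
    "IslandSummary",
    "ShoreSet",
    "summarize",
    "summary_table",
    "write_summary_tsv",
    "filter_min_length",
    "group_median_lengths",
    "compute_shores",
]

TOTAL_ID = "total"


@dataclass(frozen=True)
class IslandSummary:
    """Roll-up of the islands on one sequence (or the whole genome).

    ``freq_per_kb`` is islands per 1000 bp of sequence; ``coverage_pct``
    is the percentage of the sequence covered by island bodies (islands
    are non-overlapping, so covered bp is just the sum of lengths).
    ``median_length`` is None when there are no islands.
    """

    seq_id: str
    count: int
    total_bp: int
    median_length: float | None
    chrom_length: int

    @property
    def freq_per_kb(self) -> float:
        return self.count / self.chrom_length * 1000

    @property
    def coverage_pct(self) -> float:
        return self.total_bp / self.chrom_length * 100

    @classmethod
    def from_counts(cls, seq_id: str, count: int, total_bp: int, chrom_length: int,
                    median_length: float | None = None) -> "IslandSummary":
        """Build a summary row from already-tallied counts.

        Useful for recomputing frequency/coverage from a published table
        of counts without rerunning a genome scan.
        """
        return cls(seq_id=seq_id, count=count, total_bp=total_bp,
                   median_length=median_length, chrom_length=chrom_length)


@dataclass(frozen=True)
class ShoreSet:
    """Intervals flanking islands, excluding every island body."""

    intervals: list[tuple[str, int, int]]

    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def _median_or_none(lengths: list[int]) -> float | None:
    return float(median(lengths)) if lengths else None


def summarize(islands: Sequence[CpXIsland], chrom_sizes: dict[str, int]) -> list[IslandSummary]:
    """Per-chromosome summary rows plus a genome-total row.

    Every sequence in ``chrom_sizes`` gets a row (zero-filled when it
    carries no island); the total row pools all islands and sums the
    chromosome lengths.  The total median is taken over all island
    lengths pooled, not averaged across chromosomes.
    """
    by_chrom: dict[str, list[int]] = {name: [] for name in chrom_sizes}
    for isl in islands:
        if isl.seq_id not in chrom_sizes:
            raise ValueError(f"island on unknown sequence {isl.seq_id!r}")
        by_chrom[isl.seq_id].append(isl.length)

    rows = [
        IslandSummary(
            seq_id=name,
            count=len(lengths),
            total_bp=sum(lengths),
            median_length=_median_or_none(lengths),
            chrom_length=chrom_sizes[name],
        )
        for name, lengths in by_chrom.items()
    ]
    pooled = [isl.length for isl in islands]
    rows.append(
        IslandSummary(
            seq_id=TOTAL_ID,
            count=len(pooled),
            total_bp=sum(pooled),
            median_length=_median_or_none(pooled),
            chrom_length=sum(chrom_sizes.values()),
        )
    )
    return rows


def summary_table(rows: Iterable[IslandSummary]) -> pd.DataFrame:
    """Summary rows as a table: freq rounded to 3 decimals, coverage to 1."""
    return pd.DataFrame(
        {
            "seq_id": r.seq_id,
            "count": r.count,
            "sum_bp": r.total_bp,
            "median_length_bp": round(r.median_length) if r.median_length is not None else pd.NA,
            "freq_per_1000bp": round(r.freq_per_kb, 3),
            "coverage_pct": round(r.coverage_pct, 1),
        }
        for r in rows
    )


def write_summary_tsv(rows: Iterable[IslandSummary], path: str | PathLike) -> None:
    summary_table(rows).to_csv(path, sep="\t", index=False)


def filter_min_length(islands: Sequence[CpXIsland], min_len: int) -> list[CpXIsland]:
    """Islands at least ``min_len`` bp long (inclusive), order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [isl for isl in islands if isl.length >= min_len]


def group_median_lengths(islands: Sequence[CpXIsland],
                         group_ids: set[str]) -> tuple[float, float]:
    """Median island length inside a chromosome group vs the rest.

    Returns (median of islands on chromosomes in ``group_ids``, median
    of all other islands); raises if either group is empty.
    """
    in_group = [isl.length for isl in islands if isl.seq_id in group_ids]
    rest = [isl.length for isl in islands if isl.seq_id not in group_ids]
    if not in_group or not rest:
        raise ValueError("both chromosome groups must contain at least one island")
    return float(median(in_group)), float(median(rest))


def compute_shores(islands: Sequence[CpXIsland], chrom_sizes: dict[str, int],
                   flank: int = 2000) -> ShoreSet:
    """Flanking regions of each island, minus every island body.

    For each island the candidate shores are [start − flank, start) and
    [end, end + flank), clipped to the chromosome; overlapping shore
    fragments from adjacent islands are merged and all island bodies are
    subtracted, so shores and islands are bp-disjoint.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_chrom: dict[str, list[CpXIsland]] = {}
    for isl in islands:
        if isl.seq_id not in chrom_sizes:
            raise ValueError(f"island on unknown sequence {isl.seq_id!r}")
        by_chrom.setdefault(isl.seq_id, []).append(isl)

    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        chrom_len = chrom_sizes[chrom]
        chrom_islands = sorted(by_chrom[chrom], key=lambda i: i.start)
        candidates = []
        for isl in chrom_islands:
            up = (max(0, isl.start - flank), isl.start)
            down = (isl.end, min(chrom_len, isl.end + flank))
            for s, e in (up, down):
                if s < e:
                    candidates.append((s, e))
        merged = _merge_intervals(candidates)
        bodies = _merge_intervals([(i.start, i.end) for i in chrom_islands])
        for s, e in _subtract_intervals(merged, bodies):
            out.append((chrom, s, e))
    return ShoreSet(intervals=out)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract_intervals(intervals: list[tuple[int, int]],
                        holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out
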