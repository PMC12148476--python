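"""Takai–Jones-style sliding-window detection of CpX islands.

A CpX island is a region with elevated C+X content and an elevated
observed/expected CpX dinucleotide ratio, where the dinucleotide is a
cytosine followed by a second base X ∈ {G, A, T, C}.  Detection scans a
sequence with a fixed-width window (default 500 bp): a window *qualifies*
when its CX percentage and O/E ratio both meet their minimum thresholds
(inclusive).  Qualifying windows seed candidate islands which are
extended 3′ in window-sized jumps, rolled back base-by-base after the
first failing jump, trimmed alternately from both ends until the whole
span qualifies, and finally merged with neighbours closer than the merge
gap.

The classical CpG-island criteria correspond to the defaults: window
≥ 500 bp, CX (here GC) ≥ 55 %, O/E ≥ 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "DetectionParams",
    "WindowStats",
    "CpXIsland",
    "window_stats",
    "qualifies",
    "shift_stats",
    "find_seed",
    "extend_candidate",
    "trim_candidate",
    "merge_islands",
    "detect_islands",
    "qualification_mask",
]

_BASES = ("G", "A", "T", "C")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the island scan.

    window_size
        Width W of the scanning window and the minimum island length, bp.
    min_cx
        Minimum CX percentage as a fraction in (0, 1]: the share of bases
        in the window that are C or X (just C when X = C).
    min_oe
        Minimum observed/expected CpX ratio.  Expected count under base
        independence is count(C)·count(X)/N for a window of N bp.
    max_merge_gap
        Maximum distance in bp between two detected islands for them to
        be coalesced into one.
    second_nt
        The X of CpX.  The first nucleotide is always cytosine.
    """

    window_size: int = 500
    min_cx: float = 0.55
    min_oe: float = 0.65
    max_merge_gap: int = 100
    second_nt: str = "G"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0.0 < self.min_cx <= 1.0:
            raise ValueError("min_cx must be in (0, 1]")
        if self.min_oe <= 0.0:
            raise ValueError("min_oe must be > 0")
        if self.max_merge_gap < 0:
            raise ValueError("max_merge_gap must be >= 0")
        if self.second_nt not in _BASES:
            raise ValueError(f"second_nt must be one of {_BASES}")


@dataclass(frozen=True)
class WindowStats:
    """Base and dinucleotide counts over one span, with derived ratios.

    ``cpx_count`` counts every position i in the span (i and i+1 both
    inside) where base i is C and base i+1 is X; for X = C this counting
    is overlapping, so "CCC" contains two CpC.  Bases N are neither C nor
    X and dinucleotides containing N never count.  When X = C,
    ``x_count`` equals ``c_count`` by convention.
    """

    c_count: int
    x_count: int
    cpx_count: int
    span_len: int
    second_nt: str

    @property
    def cx_percent(self) -> float:
        """Fraction of span bases that are C or X (C alone when X = C)."""
        if self.second_nt == "C":
            return self.c_count / self.span_len
        return (self.c_count + self.x_count) / self.span_len

    @property
    def oe_ratio(self) -> float:
        """Observed CpX count over count(C)·count(X)/N; 0 when C·X = 0."""
        denom = self.c_count * self.x_count
        if denom == 0:
            return 0.0
        return self.cpx_count * self.span_len / denom


@dataclass(frozen=True)
class CpXIsland:
    """A detected island: 0-based half-open interval plus its statistics.

    ``merged_from`` records how many pre-merge components the island was
    coalesced from; an unmerged island (merged_from == 1) satisfies both
    detection thresholds, a merged one need not.
    """

    seq_id: str
    start: int
    end: int
    cx_percent: float
    oe_ratio: float
    second_nt: str
    merged_from: int = 1
    sequence: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid island interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def jaccard(self, start: int, end: int) -> float:
        """Jaccard overlap between this island and another interval."""
        inter = max(0, min(self.end, end) - max(self.start, start))
        union = (self.end - self.start) + (end - start) - inter
        return inter / union if union else 0.0


class _Scan:
    """Prefix-sum counts over one sequence for O(1) window statistics."""

    def __init__(self, seq: str, second_nt: str):
        self.second_nt = second_nt
        self.length = len(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_x = is_c if second_nt == "C" else arr == ord(second_nt)
        is_cpx = is_c[:-1] & is_x[1:] if self.length > 1 else np.zeros(0, dtype=bool)
        self._cum_c = np.concatenate(([0], np.cumsum(is_c, dtype=np.int64)))
        self._cum_x = self._cum_c if second_nt == "C" else np.concatenate(
            ([0], np.cumsum(is_x, dtype=np.int64))
        )
        self._cum_d = np.concatenate(([0], np.cumsum(is_cpx, dtype=np.int64)))

    def stats(self, start: int, end: int) -> WindowStats:
        if not 0 <= start < end <= self.length:
            raise ValueError(f"span [{start}, {end}) out of range for length {self.length}")
        return WindowStats(
            c_count=int(self._cum_c[end] - self._cum_c[start]),
            x_count=int(self._cum_x[end] - self._cum_x[start]),
            cpx_count=int(self._cum_d[end - 1] - self._cum_d[start]),
            span_len=end - start,
            second_nt=self.second_nt,
        )

    def qualifies(self, start: int, end: int, params: DetectionParams) -> bool:
        return qualifies(self.stats(start, end), params)

    def mask(self, params: DetectionParams) -> np.ndarray:
        """Qualification of every W-window, vectorized over all starts."""
        W = params.window_size
        n = self.length - W + 1
        if n <= 0:
            return np.zeros(0, dtype=bool)
        c = self._cum_c[W:] - self._cum_c[:-W]
        x = self._cum_x[W:] - self._cum_x[:-W]
        d = self._cum_d[W - 1 : W - 1 + n] - self._cum_d[:n]
        if self.second_nt == "C":
            cx_pct = c / W
        else:
            cx_pct = (c + x) / W
        denom = c * x
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(denom > 0, d * W / np.where(denom > 0, denom, 1), 0.0)
        return (cx_pct >= params.min_cx) & (oe >= params.min_oe)


def window_stats(record: SequenceRecord, start: int, end: int, second_nt: str = "G") -> WindowStats:
    """Count bases and CpX dinucleotides fully inside [start, end).

    Direct recount of the span; use :func:`shift_stats` or
    :func:`detect_islands` for repeated queries on one sequence.
    """
    if not 0 <= start < end <= record.length:
        raise ValueError(f"span [{start}, {end}) out of range for {record.id!r}")
    sub = record.seq[start:end]
    c = sub.count("C")
    if second_nt == "C":
        x = c
    else:
        x = sub.count(second_nt)
    cpx = sum(1 for i in range(len(sub) - 1) if sub[i] == "C" and sub[i + 1] == second_nt)
    return WindowStats(c_count=c, x_count=x, cpx_count=cpx, span_len=end - start,
                       second_nt=second_nt)


def qualifies(stats: WindowStats, params: DetectionParams) -> bool:
    """True iff CX% and O/E both meet their minima (inclusive)."""
    return stats.cx_percent >= params.min_cx and stats.oe_ratio >= params.min_oe


def shift_stats(stats: WindowStats, record: SequenceRecord, old_start: int,
                second_nt: str = "G") -> WindowStats:
    """Stats for the window shifted right by 1 bp, in constant work.

    Removes the contribution of the leaving 5′ base and its dinucleotide
    and adds the entering 3′ base and the dinucleotide it completes; the
    result is identical to a full recount of the shifted window.
    """
    n = stats.span_len
    if old_start + 1 + n > record.length:
        raise ValueError("cannot shift window past the end of the sequence")
    seq = record.seq
    c, x, cpx = stats.c_count, stats.x_count, stats.cpx_count
    x_is_c = second_nt == "C"

    leaving = seq[old_start]
    if leaving == "C":
        c -= 1
        if x_is_c:
            x -= 1
    if not x_is_c and leaving == second_nt:
        x -= 1
    if seq[old_start] == "C" and seq[old_start + 1] == second_nt:
        cpx -= 1

    entering = seq[old_start + n]
    if entering == "C":
        c += 1
        if x_is_c:
            x += 1
    if not x_is_c and entering == second_nt:
        x += 1
    if seq[old_start + n - 1] == "C" and entering == second_nt:
        cpx += 1

    return WindowStats(c_count=c, x_count=x, cpx_count=cpx, span_len=n, second_nt=second_nt)


def qualification_mask(record: SequenceRecord, params: DetectionParams) -> np.ndarray:
    """Boolean vector: does the W-window starting at each position qualify?

    Computed from running prefix counts in a single pass; positions run
    from 0 to record.length − W inclusive.
    """
    return _Scan(record.seq, params.second_nt).mask(params)


def _find_seed(mask: np.ndarray, from_pos: int) -> int | None:
    if from_pos >= len(mask):
        return None
    from_pos = max(from_pos, 0)
    rel = int(np.argmax(mask[from_pos:]))
    if not mask[from_pos + rel]:
        return None
    return from_pos + rel


def find_seed(record: SequenceRecord, from_pos: int, params: DetectionParams) -> int | None:
    """Smallest s ≥ from_pos whose W-window qualifies, or None."""
    if from_pos < 0:
        raise ValueError("from_pos must be >= 0")
    scan = _Scan(record.seq, params.second_nt)
    return _find_seed(scan.mask(params), from_pos)


def _extend(scan: _Scan, mask: np.ndarray, seed: int, params: DetectionParams) -> tuple[int, int]:
    W = params.window_size
    last_start = len(mask) - 1  # last valid window start
    prev = seed
    while True:
        cand = prev + W
        if cand <= last_start and mask[cand]:
            prev = cand
            continue
        # First failing jump (or sequence end): roll the failing window
        # back 1 bp at a time toward 5', stopping at the previous
        # qualifying window's start.
        t = min(cand, last_start)
        while t > prev and not mask[t]:
            t -= 1
        return seed, t + W


def extend_candidate(record: SequenceRecord, seed: int, params: DetectionParams) -> tuple[int, int]:
    """Extend a qualifying seed window 3′ by window-sized jumps.

    Jumps of exactly W continue while each displaced window qualifies;
    after the first failure the failing window rolls back base-by-base
    until it qualifies (or reaches the previous qualifying window).  The
    candidate spans the seed start to the last qualifying window's end.
    """
    scan = _Scan(record.seq, params.second_nt)
    mask = scan.mask(params)
    if not (0 <= seed < len(mask)) or not mask[seed]:
        raise ValueError(f"seed window at {seed} does not qualify")
    return _extend(scan, mask, seed, params)


def _trim(scan: _Scan, span: tuple[int, int], params: DetectionParams,
          seq_id: str) -> CpXIsland:
    W = params.window_size
    s0, e0 = span
    s, e = s0, e0

    def island(a: int, b: int, merged_from: int = 1) -> CpXIsland:
        st = scan.stats(a, b)
        return CpXIsland(seq_id=seq_id, start=a, end=b, cx_percent=st.cx_percent,
                         oe_ratio=st.oe_ratio, second_nt=params.second_nt,
                         merged_from=merged_from)

    if scan.qualifies(s, e, params):
        return island(s, e)
    trim_5prime = True
    while e - s > W:
        if trim_5prime:
            s += 1
        else:
            e -= 1
        trim_5prime = not trim_5prime
        if scan.qualifies(s, e, params):
            return island(s, e)
    # Alternate trimming bottomed out at width W: fall back to the
    # 5'-most qualifying W-window of the original span (the seed window,
    # which qualified by construction, guarantees one exists).
    for t in range(s0, e0 - W + 1):
        if scan.qualifies(t, t + W, params):
            return island(t, t + W)
    raise ValueError(f"span [{s0}, {e0}) contains no qualifying window")


def trim_candidate(record: SequenceRecord, span: tuple[int, int],
                   params: DetectionParams) -> CpXIsland:
    """Shrink a candidate span until it qualifies as a whole.

    If the full span already qualifies it is returned unchanged;
    otherwise 1 bp is trimmed alternately from the 5′ then the 3′ end,
    re-testing after each trim, down to width W.  Statistics are
    recomputed over the final coordinates.
    """
    scan = _Scan(record.seq, params.second_nt)
    return _trim(scan, span, params, record.id)


def _check_mergeable(islands: Sequence[CpXIsland]) -> None:
    for prev, nxt in zip(islands, islands[1:]):
        if prev.seq_id != nxt.seq_id:
            raise ValueError("merge_islands expects islands on a single sequence")
        if nxt.start < prev.end:
            raise ValueError(
                f"islands [{prev.start},{prev.end}) and [{nxt.start},{nxt.end}) "
                "overlap or are unsorted"
            )


def merge_islands(record: SequenceRecord, islands: Sequence[CpXIsland],
                  params: DetectionParams) -> list[CpXIsland]:
    """Coalesce consecutive islands separated by ≤ max_merge_gap bp.

    Merging is unconditional and transitive: the merged interval spans
    the first component's start to the last one's end and its CX% and
    O/E are recomputed over that whole span, without re-testing the
    thresholds.  Gaps are measured in half-open coordinates
    (next.start − prev.end).
    """
    _check_mergeable(islands)
    if not islands:
        return []
    scan = _Scan(record.seq, params.second_nt)
    merged: list[CpXIsland] = []
    group = [islands[0]]
    for isl in islands[1:]:
        if isl.start - group[-1].end <= params.max_merge_gap:
            group.append(isl)
        else:
            merged.append(_coalesce(scan, group, params))
            group = [isl]
    merged.append(_coalesce(scan, group, params))
    return merged


def _coalesce(scan: _Scan, group: list[CpXIsland], params: DetectionParams) -> CpXIsland:
    if len(group) == 1:
        return group[0]
    start, end = group[0].start, group[-1].end
    st = scan.stats(start, end)
    return CpXIsland(
        seq_id=group[0].seq_id, start=start, end=end,
        cx_percent=st.cx_percent, oe_ratio=st.oe_ratio,
        second_nt=params.second_nt,
        merged_from=sum(g.merged_from for g in group),
    )


def detect_islands(record: SequenceRecord, params: DetectionParams | None = None,
                   attach_sequences: bool = True) -> list[CpXIsland]:
    """Detect all CpX islands in one sequence record.

    Orchestrates seed search → jump extension → alternate trimming,
    resuming the seed search at each accepted island's end, then merges
    islands closer than the merge gap.  Returns islands sorted by start,
    non-overlapping, each at least window_size bp long.  A record
    shorter than the window yields an empty list.
    """
    params = params or DetectionParams()
    W = params.window_size
    if record.length < W:
        return []
    scan = _Scan(record.seq, params.second_nt)
    mask = scan.mask(params)

    raw: list[CpXIsland] = []
    pos = 0
    while True:
        seed = _find_seed(mask, pos)
        if seed is None:
            break
        span = _extend(scan, mask, seed, params)
        isl = _trim(scan, span, params, record.id)
        raw.append(isl)
        pos = isl.end
    merged = merge_islands(record, raw, params)
    if attach_sequences:
        merged = [replace(isl, sequence=record.seq[isl.start:isl.end]) for isl in merged]
    return merged
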