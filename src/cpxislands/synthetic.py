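"""Synthetic genomes with controlled dinucleotide structure.

Order-1 Markov chains over {A, C, G, T} generate background sequence and
planted island segments.  Order 1 matters: the CX percentage and the
observed/expected CpX ratio respond to dinucleotide transition structure,
which an i.i.d. base sampler cannot shape.  The default background
suppresses C→X transitions (emulating the CpX depletion that makes
islands stand out in real genomes) while the default island model raises
both C/X content and P(X | C).

All sampling is driven by :class:`numpy.random.Generator` (PCG64) seeded
from explicit integers, so identical seeds reproduce identical sequences
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DetectionParams
from .seqio import SequenceRecord

__all__ = [
    "MarkovModel",
    "PlantedTruth",
    "background_model",
    "island_model",
    "generate_markov",
    "plant_islands",
    "naive_qualification_mask",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MarkovModel:
    """First-order base chain: initial distribution + 4×4 transition matrix.

    Rows and columns are ordered A, C, G, T; every row must be a
    probability vector (sum 1 within 1e-9, entries ≥ 0).
    """

    initial: tuple[float, float, float, float]
    transition: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if init.shape != (4,) or trans.shape != (4, 4):
            raise ValueError("initial must have 4 entries and transition be 4x4")
        rows = np.vstack([init, trans])
        if (rows < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1 within 1e-9")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.initial, dtype=float),
                np.asarray(self.transition, dtype=float))


def _row_with_cx(base_probs: dict[str, float], second_nt: str, p_cx: float) -> tuple:
    """Transition row from C: force P(X|C)=p_cx, rescale the rest."""
    rest = {b: p for b, p in base_probs.items() if b != second_nt}
    scale = (1.0 - p_cx) / sum(rest.values())
    row = {b: p * scale for b, p in rest.items()}
    row[second_nt] = p_cx
    return tuple(row[b] for b in BASES)


def background_model(second_nt: str = "G", p_cx: float = 0.05) -> MarkovModel:
    """Island-free background: mildly AT-rich (42% GC) with C→X suppressed.

    42% GC matches a typical fly-like euchromatic composition; p_cx=0.05
    keeps background windows far below the default O/E threshold.
    """
    base = {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}
    row = tuple(base[b] for b in BASES)
    rows = [row, _row_with_cx(base, second_nt, p_cx), row, row]
    return MarkovModel(initial=row, transition=tuple(rows))


def island_model(second_nt: str = "G") -> MarkovModel:
    """Island segments: C/X-enriched bases with P(X | C) = 0.5.

    Calibrated so a 500-bp window of pure island sequence passes the
    default thresholds (CX ≥ 0.55, O/E ≥ 0.65) with wide margin; when
    X = C the model is simply strongly C-rich (O/E ≈ 1 by construction).
    """
    if second_nt == "C":
        base = {"A": 0.38 / 3, "C": 0.62, "G": 0.38 / 3, "T": 0.38 / 3}
        row = tuple(base[b] for b in BASES)
        return MarkovModel(initial=row, transition=(row, row, row, row))
    others = [b for b in "AGT" if b != second_nt]
    base = {"C": 0.35, second_nt: 0.30, others[0]: 0.175, others[1]: 0.175}
    row = tuple(base[b] for b in BASES)
    from_c = {"C": 0.25, second_nt: 0.50, others[0]: 0.125, others[1]: 0.125}
    rows = [row, tuple(from_c[b] for b in BASES), row, row]
    return MarkovModel(initial=row, transition=tuple(rows))


def _sample_chain(model: MarkovModel, length: int, rng: np.random.Generator) -> str:
    init, trans = model.as_arrays()
    cum_init = np.cumsum(init)
    cum_trans = np.cumsum(trans, axis=1)
    draws = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(cum_init, draws[0], side="right"))
    state = min(state, 3)
    out[0] = state
    for i in range(1, length):
        state = int(np.searchsorted(cum_trans[state], draws[i], side="right"))
        state = min(state, 3)
        out[i] = state
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def generate_markov(model: MarkovModel, length: int,
                    rng_seed: int | np.random.Generator,
                    seq_id: str = "synthetic") -> SequenceRecord:
    """Sample one sequence base-by-base from a first-order chain."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    return SequenceRecord(id=seq_id, seq=_sample_chain(model, length, rng))


@dataclass(frozen=True)
class PlantedTruth:
    """A synthetic record together with where island segments were planted."""

    record: SequenceRecord
    truth_intervals: list[tuple[int, int]]
    background_model: MarkovModel
    island_model: MarkovModel
    rng_seed: int


def plant_islands(background_len: int,
                  island_specs: Sequence[tuple[int, int]],
                  background_model: MarkovModel,
                  island_model: MarkovModel,
                  rng_seed: int,
                  seq_id: str = "synthetic") -> PlantedTruth:
    """Generate background sequence and replace segments with island model.

    ``island_specs`` is a list of (position, length) pairs; segments must
    fit inside the background without overlapping.  Background and each
    segment are drawn from independent child streams of ``rng_seed``, so
    the same seed always reproduces the same record.
    """
    specs = sorted((int(p), int(L)) for p, L in island_specs)
    for (p, L) in specs:
        if p < 0 or L < 1 or p + L > background_len:
            raise ValueError(f"island segment ({p}, {L}) does not fit in background")
    for (p1, l1), (p2, _) in zip(specs, specs[1:]):
        if p1 + l1 > p2:
            raise ValueError("island segments overlap")

    streams = np.random.SeedSequence(rng_seed).spawn(1 + len(specs))
    seq = list(_sample_chain(background_model, background_len,
                             np.random.default_rng(streams[0])))
    truth = []
    for (p, L), ss in zip(specs, streams[1:]):
        seq[p:p + L] = _sample_chain(island_model, L, np.random.default_rng(ss))
        truth.append((p, p + L))
    return PlantedTruth(
        record=SequenceRecord(id=seq_id, seq="".join(seq)),
        truth_intervals=truth,
        background_model=background_model,
        island_model=island_model,
        rng_seed=rng_seed,
    )


def naive_qualification_mask(record: SequenceRecord, params: DetectionParams) -> np.ndarray:
    """Window qualification computed by full recount at every start.

    Independent oracle for the scanner: every window's base and
    dinucleotide counts are summed from scratch (no rolling state or
    prefix sums), then tested against the thresholds.
    """
    W = params.window_size
    if record.length < W:
        raise ValueError("record shorter than the window")
    arr = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    x_is_c = params.second_nt == "C"
    is_x = is_c if x_is_c else (arr == ord(params.second_nt)).astype(np.int64)
    is_cpx = is_c[:-1] * is_x[1:]

    win = np.lib.stride_tricks.sliding_window_view
    c = win(is_c, W).sum(axis=1)
    x = win(is_x, W).sum(axis=1)
    d = win(is_cpx, W - 1).sum(axis=1)

    cx_pct = (c / W) if x_is_c else ((c + x) / W)
    denom = c * x
    oe = np.where(denom > 0, d * W / np.where(denom > 0, denom, 1), 0.0)
    return (cx_pct >= params.min_cx) & (oe >= params.min_oe)
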