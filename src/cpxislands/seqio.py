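"""FASTA input and BED/BedGraph/CSV output for island intervals.

Coordinate conventions follow the genome-browser standards: BED and
BedGraph are 0-based half-open; the CSV export is 1-based inclusive.
All island coordinates held in memory are 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "FastaFormatError",
    "read_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "write_csv",
    "read_features",
]

# Everything outside the unambiguous DNA alphabet (IUPAC ambiguity codes,
# gap characters, ...) collapses to N: whole-genome FASTA routinely
# contains such characters and they must not abort a scan.
_VALID = set("ACGTN")
_NORMALIZE = {ord(c): "N" for c in map(chr, range(256)) if c.upper() not in _VALID}
_NORMALIZE.update({ord(c): c.upper() for c in "acgtnACGTN"})


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``seq`` is uppercased with ambiguity codes mapped to N.
    """

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and map any non-ACGTN character to N."""
    return raw.translate(_NORMALIZE)


def read_fasta(path: str | PathLike) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord`\\ s.

    Records are returned in file order.  Raises :class:`FastaFormatError`
    on an empty file, an empty header, a record with no sequence, or a
    duplicated id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                if not rec.id:
                    raise FastaFormatError(f"{path}: record with empty header")
                seq = normalize_sequence(str(rec.seq))
                if not seq:
                    raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
                if rec.id in seen:
                    raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
                seen.add(rec.id)
                records.append(SequenceRecord(id=rec.id, seq=seq))
        except FastaFormatError:
            raise
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def read_chrom_sizes(path: str | PathLike) -> dict[str, int]:
    """Read a two-column TSV of sequence id and length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {name!r}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | PathLike) -> None:
    with open(path, "w") as handle:
        for name, length in sizes.items():
            handle.write(f"{name}\t{length}\n")


def _check_sorted(islands: Sequence) -> None:
    keys = [(isl.seq_id, isl.start) for isl in islands]
    if keys != sorted(keys):
        raise ValueError("islands must be sorted by (seq_id, start) before writing")


def write_bed(islands: Sequence, path: str | PathLike) -> None:
    """Write islands as BED4+3: chrom, start, end, name, CX%, O/E, length.

    Starts are 0-based, ends half-open; names are ``Cp<X>_<n>`` numbered
    in file order from 1.  Input must already be sorted by
    (seq_id, start); sorting is the caller's job, which keeps the writer
    a pure serializer.
    """
    _check_sorted(islands)
    with open(path, "w") as handle:
        for n, isl in enumerate(islands, 1):
            name = f"Cp{isl.second_nt}_{n}"
            handle.write(
                f"{isl.seq_id}\t{isl.start}\t{isl.end}\t{name}"
                f"\t{isl.cx_percent:.4f}\t{isl.oe_ratio:.4f}\t{isl.length}\n"
            )


def read_bed(path: str | PathLike):
    """Read a BED4+3 file written by :func:`write_bed` back into islands."""
    from .core import CpXIsland  # local import to avoid a cycle

    islands = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            chrom, start, end, name, cx, oe, length = fields
            second_nt = name.split("_")[0].removeprefix("Cp")
            isl = CpXIsland(
                seq_id=chrom,
                start=int(start),
                end=int(end),
                cx_percent=float(cx),
                oe_ratio=float(oe),
                second_nt=second_nt,
            )
            if isl.length != int(length):
                raise ValueError(f"{path}:{lineno}: length column disagrees with coordinates")
            islands.append(isl)
    return islands


_BEDGRAPH_FIELDS = ("cx_percent", "oe_ratio")


def write_bedgraph(islands: Sequence, path: str | PathLike, value_field: str = "cx_percent") -> None:
    """Write strict 4-column BedGraph carrying one numeric value per island.

    BedGraph admits a single value column, so ``value_field`` selects
    which island statistic to export (``cx_percent`` or ``oe_ratio``).
    """
    if value_field not in _BEDGRAPH_FIELDS:
        raise ValueError(
            f"value_field must be one of {_BEDGRAPH_FIELDS}, got {value_field!r}"
        )
    _check_sorted(islands)
    with open(path, "w") as handle:
        for isl in islands:
            value = getattr(isl, value_field)
            handle.write(f"{isl.seq_id}\t{isl.start}\t{isl.end}\t{value:.4f}\n")


def write_csv(islands: Sequence, path: str | PathLike, seq_preview_len: int = 40) -> None:
    """Write islands as CSV with 1-based inclusive coordinates.

    Columns: seq_id, start_1based, end_1based, sequence_preview,
    cx_percent, oe_ratio, length_bp.  The preview shows the first
    ``seq_preview_len`` bases and is suffixed with an ellipsis when the
    island is longer; islands lacking an attached sequence get an empty
    preview.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["seq_id", "start_1based", "end_1based", "sequence_preview",
             "cx_percent", "oe_ratio", "length_bp"]
        )
        for isl in islands:
            seq = getattr(isl, "sequence", None) or ""
            preview = seq[:seq_preview_len] + ("…" if len(seq) > seq_preview_len else "")
            writer.writerow(
                [isl.seq_id, isl.start + 1, isl.end, preview,
                 f"{isl.cx_percent:.4f}", f"{isl.oe_ratio:.4f}", isl.length]
            )


def write_fasta(records: Iterable[SequenceRecord], path: str | PathLike,
                width: int = 60) -> None:
    """Write records as FASTA wrapped to ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.seq[i : i + width] + "\n")


def write_intervals_bed(intervals: Iterable[tuple[str, int, int]],
                        path: str | PathLike) -> None:
    """Write bare (chrom, start, end) triples as BED3."""
    with open(path, "w") as handle:
        for chrom, start, end in intervals:
            handle.write(f"{chrom}\t{start}\t{end}\n")


def read_features(path: str | PathLike) -> list:
    """Read annotation features from BED3+1 (chrom, start, end, type label)."""
    from .overlap import GenomicFeature

    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 columns")
            features.append(
                GenomicFeature(
                    seq_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    type_label=fields[3],
                )
            )
    return features
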