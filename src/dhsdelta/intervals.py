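"""Genomic coordinate primitives and BED I/O.

All coordinates are 0-based half-open (BED convention). Strand is carried
but ignored by overlap and signal arithmetic; only transcription start
sites are strand-aware.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed; names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Site center, floor((start + end) / 2)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a strand-aware TSS and sorted, non-overlapping exons."""

    gene_id: str
    tss: int
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        if sorted(starts) != starts or any(
            ends[i] > starts[i + 1] for i in range(len(self.exons) - 1)
        ):
            raise ValueError("exons must be sorted and non-overlapping")
        expected = starts[0] if self.strand == "+" else ends[-1]
        if self.tss != expected:
            raise ValueError(
                f"tss {self.tss} does not match {self.strand}-strand exon "
                f"boundary {expected}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file (gzip-transparent).

    Lines beginning with ``track``, ``browser`` or ``#`` are skipped.
    Coordinates are taken verbatim (BED is already 0-based half-open).
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (missing name/score rendered as '.')."""
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            score = "." if iv.score is None else repr(iv.score)
            name = "." if iv.name is None else iv.name
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """Half-open overlap test requiring at least ``min_overlap`` shared bases."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


def _by_chrom(ivs: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """chrom -> (n, 2) sorted start/end array."""
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        groups.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in groups.items()
    }


def overlapping_mask(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean per interval of ``set_a``: overlaps any interval in ``set_b``.

    Sorted-sweep with a prefix maximum of end coordinates; O((n+m) log m).
    """
    b = _by_chrom(set_b)
    prefmax = {c: np.maximum.accumulate(arr[:, 1]) for c, arr in b.items()}
    out = np.zeros(len(set_a), dtype=bool)
    for i, a in enumerate(set_a):
        arr = b.get(a.chrom)
        if arr is None:
            continue
        if min_overlap == 1:
            k = np.searchsorted(arr[:, 0], a.end, side="left")
            out[i] = k > 0 and prefmax[a.chrom][k - 1] >= a.start + 1
        else:
            ov = np.minimum(arr[:, 1], a.end) - np.maximum(arr[:, 0], a.start)
            out[i] = bool(np.any(ov >= min_overlap))
    return out


def count_overlapping(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> int:
    """Number of intervals in ``set_a`` overlapped by at least one in ``set_b``."""
    return int(overlapping_mask(set_a, set_b, min_overlap).sum())


def nearest_coordinate(
    sorted_coords: np.ndarray, query: int
) -> tuple[int, int]:
    """(index, distance) of the coordinate nearest ``query``.

    Ties break toward the smaller coordinate. ``sorted_coords`` must be
    ascending and nonempty.
    """
    coords = sorted_coords
    j = int(np.searchsorted(coords, query))
    best_i, best_d = None, None
    for i in (j - 1, j):
        if 0 <= i < len(coords):
            d = abs(int(coords[i]) - query)
            if best_d is None or d < best_d:
                best_i, best_d = i, d
    return best_i, best_d
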