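"""Piecewise-constant signal tracks (bedGraph semantics).

A SignalTrack stores, per chromosome, sorted non-overlapping runs of
constant value. Positions not covered by any run have value 0. This is
the in-memory form of a fragment-pileup bedGraph as emitted by peak
callers, and it backs all signal aggregation in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, _open_text


class TrackValidationError(ValueError):
    pass


@dataclass
class _ChromRuns:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray
    values: np.ndarray  # float64, >= 0
    # cumulative signal weight: cw[i] = sum_{j<i} values[j] * length[j]
    cw: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lengths = self.ends - self.starts
        self.cw = np.concatenate(
            ([0.0], np.cumsum(self.values * lengths))
        )


class SignalTrack:
    """Per-base signal as sorted non-overlapping constant runs."""

    def __init__(
        self,
        runs: Iterable[tuple[str, int, int, float]] = (),
        mapped_reads: int | None = None,
    ):
        grouped: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if value < 0:
                raise TrackValidationError(
                    f"negative value {value} at {chrom}:{start}-{end}"
                )
            if start >= end:
                raise TrackValidationError(
                    f"empty run at {chrom}:{start}-{end}"
                )
            grouped.setdefault(chrom, []).append((start, end, value))
        self._chroms: dict[str, _ChromRuns] = {}
        for chrom, rs in grouped.items():
            rs.sort()
            arr = np.array(rs, dtype=np.float64).reshape(-1, 3)
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise TrackValidationError(
                    f"overlapping runs on {chrom} near offset {starts[bad + 1]}"
                )
            self._chroms[chrom] = _ChromRuns(starts, ends, arr[:, 2])
        self.mapped_reads = mapped_reads

    @classmethod
    def from_arrays(
        cls,
        chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        mapped_reads: int | None = None,
    ) -> "SignalTrack":
        """Build directly from per-chromosome sorted (starts, ends, values)."""
        t = cls.__new__(cls)
        t._chroms = {}
        for chrom, (s, e, v) in chrom_arrays.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if np.any(v < 0):
                raise TrackValidationError(f"negative values on {chrom}")
            if np.any(s >= e) or np.any(s[1:] < e[:-1]):
                raise TrackValidationError(f"bad run layout on {chrom}")
            t._chroms[chrom] = _ChromRuns(s, e, v)
        t.mapped_reads = mapped_reads
        return t

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cr = self._chroms[chrom]
        return cr.starts, cr.ends, cr.values

    def iter_runs(self):
        for chrom in self.chroms:
            cr = self._chroms[chrom]
            for s, e, v in zip(cr.starts, cr.ends, cr.values):
                yield chrom, int(s), int(e), float(v)

    @property
    def total_signal(self) -> float:
        return float(sum(cr.cw[-1] for cr in self._chroms.values()))

    def extent(self, chrom: str) -> tuple[int, int] | None:
        cr = self._chroms.get(chrom)
        if cr is None or len(cr.starts) == 0:
            return None
        return int(cr.starts[0]), int(cr.ends[-1])

    # --- aggregation -----------------------------------------------------

    def _weight_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Total signal in [0, pos) for an array of positions."""
        cr = self._chroms.get(chrom)
        if cr is None:
            return np.zeros(len(pos), dtype=np.float64)
        k = np.searchsorted(cr.starts, pos, side="left")
        w = cr.cw[k]
        # subtract the part of the last started run that lies at/after pos
        has_prev = k > 0
        kp = np.where(has_prev, k - 1, 0)
        tail = cr.values[kp] * np.clip(cr.ends[kp] - pos, 0, None)
        return w - np.where(has_prev, tail, 0.0)

    def batch_sum(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Sum of per-base values over many [start, end) windows (vectorized)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._weight_at(chrom, ends) - self._weight_at(chrom, starts)

    def interval_sums(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        out = np.zeros(len(intervals), dtype=np.float64)
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            s = np.array([intervals[i].start for i in idx], dtype=np.int64)
            e = np.array([intervals[i].end for i in idx], dtype=np.int64)
            out[idx] = self.batch_sum(chrom, s, e)
        return out


def aggregate_signal(
    track: SignalTrack, interval: GenomicInterval, stat: str = "sum"
) -> float:
    """Aggregate per-base signal over an interval; uncovered bases count as 0.

    ``stat`` is one of ``sum``, ``mean``, ``max``.
    """
    if stat not in ("sum", "mean", "max"):
        raise ValueError(f"unknown stat {stat!r}")
    total = float(
        track.batch_sum(
            interval.chrom,
            np.array([interval.start]),
            np.array([interval.end]),
        )[0]
    )
    if stat == "sum":
        return total
    if stat == "mean":
        return total / interval.length
    # max over per-base values, including implicit zeros at uncovered bases
    cr = track._chroms.get(interval.chrom)
    if cr is None:
        return 0.0
    lo = np.searchsorted(cr.ends, interval.start, side="right")
    hi = np.searchsorted(cr.starts, interval.end, side="left")
    if hi <= lo:
        return 0.0
    ov = np.minimum(cr.ends[lo:hi], interval.end) - np.maximum(
        cr.starts[lo:hi], interval.start
    )
    covered = int(ov.sum())
    best = float(cr.values[lo:hi].max())
    if covered < interval.length:
        best = max(best, 0.0)
    return best


def read_bedgraph(path, mapped_reads: int | None = None) -> SignalTrack:
    """Read a 4-column bedGraph (gzip-transparent); runs may be unsorted.

    Overlapping runs or negative values raise ``TrackValidationError``.
    """
    runs = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackValidationError(
                    f"line {lineno}: expected 4 columns"
                )
            try:
                runs.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise TrackValidationError(f"line {lineno}: {exc}") from exc
    return SignalTrack(runs, mapped_reads=mapped_reads)


def write_bedgraph(track: SignalTrack, path) -> None:
    import pandas as pd

    with _open_text(path, "wt") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            # default float formatting is the shortest repr, so values
            # round-trip bit-exactly through read_bedgraph
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": values}
            ).to_csv(fh, sep="\t", header=False, index=False)


def depth_normalize(track: SignalTrack) -> SignalTrack:
    """Scale run values to reads-per-million: value * 1e6 / mapped_reads."""
    if not track.mapped_reads or track.mapped_reads <= 0:
        raise ValueError(
            "mapped_reads not set; supply the library depth before "
            "depth-normalizing"
        )
    scale = 1e6 / track.mapped_reads
    arrays = {
        chrom: (s.copy(), e.copy(), v * scale)
        for chrom, (s, e, v) in (
            (c, track.runs(c)) for c in track.chroms
        )
    }
    return SignalTrack.from_arrays(arrays, mapped_reads=track.mapped_reads)
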