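"""Read 5'-end position counts and the PCR-artifact filter.

DNase-seq libraries occasionally contain PCR stacks: large numbers of
reads whose 5' ends map to a single base with little support nearby.
The filter removes all reads at a base when they account for more than
``max_frac`` of the 5'-end counts within a centered window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PositionCounts:
    """Per-chromosome sparse map of base position -> read 5'-end count."""

    data: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, d in self.data.items():
            for pos, c in d.items():
                if c < 0 or int(c) != c:
                    raise ValueError(
                        f"count at {chrom}:{pos} must be a non-negative integer"
                    )

    def add(self, chrom: str, pos: int, count: int = 1) -> None:
        d = self.data.setdefault(chrom, {})
        d[pos] = d.get(pos, 0) + count

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.data.values())


def filter_pcr_artifacts(
    counts: PositionCounts, window: int = 31, max_frac: float = 0.70
) -> PositionCounts:
    """Drop positions whose reads exceed ``max_frac`` of their window total.

    For each position p with count c > 0, the window is centered on p
    (window // 2 bases each side). If c / (total count in window) is
    strictly greater than ``max_frac``, all reads at p are removed.
    Every window is evaluated against the original counts before any
    removal, so the result is independent of evaluation order.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if not (0 < max_frac < 1) and max_frac != 1.0:
        raise ValueError("max_frac must be in (0, 1]")
    half = window // 2
    out: dict[str, dict[int, int]] = {}
    for chrom, d in counts.data.items():
        positions = np.array(sorted(d), dtype=np.int64)
        vals = np.array([d[p] for p in positions], dtype=np.int64)
        csum = np.concatenate(([0], np.cumsum(vals)))
        lo = np.searchsorted(positions, positions - half, side="left")
        hi = np.searchsorted(positions, positions + half, side="right")
        window_total = csum[hi] - csum[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.true_divide(vals, window_total)
        keep = ~((vals > 0) & (frac > max_frac))
        out[chrom] = {
            int(p): int(v) for p, v in zip(positions[keep], vals[keep])
        }
    return PositionCounts(out)
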