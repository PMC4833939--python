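"""Occupancy and signal-profile statistics around DHS sites.

Overlap proportions between site classes and peak sets, depth-normalized
signal correlation at peaks, mean signal metaprofiles around site
centers, and rank-sum comparisons of per-site fold-change distributions
between classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import cumulative_curves, rank_sum_shift
from .intervals import GenomicInterval, overlapping_mask
from .signal import SignalTrack


def overlap_proportions(
    dhs_classes: dict[str, list[GenomicInterval]],
    peaks: list[GenomicInterval],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Per class: n sites, n overlapped by >=1 peak, and the proportion.

    Empty classes get proportion NaN and are flagged.
    """
    rows = []
    for label, sites in dhs_classes.items():
        n = len(sites)
        if n == 0:
            rows.append((label, 0, 0, np.nan, True))
            continue
        k = int(overlapping_mask(sites, peaks, min_overlap).sum())
        rows.append((label, n, k, k / n, False))
    return pd.DataFrame(
        rows, columns=["class", "n", "n_overlap", "proportion", "empty"]
    )


def peak_signal_correlation(
    track_a: SignalTrack,
    track_b: SignalTrack,
    peaks: list[GenomicInterval],
    method: str = "spearman",
) -> float:
    """Rank correlation of per-peak total signal between two tracks.

    Tracks should already be depth-normalized; ties get average ranks.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks for a correlation")
    a = track_a.interval_sums(peaks)
    b = track_b.interval_sums(peaks)
    if method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho)


@dataclass
class MetaProfile:
    """Mean signal per bin around aligned site centers."""

    assay: str
    site_class: str
    halfwidth: int
    binsize: int
    mean: np.ndarray  # per bin
    sem: np.ndarray  # across sites, per bin
    n_sites: int
    n_dropped: int

    @property
    def offsets(self) -> np.ndarray:
        """Bin-center offsets relative to the site center."""
        nbins = 2 * self.halfwidth // self.binsize
        return (np.arange(nbins) + 0.5) * self.binsize - self.halfwidth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assay": self.assay,
                "site_class": self.site_class,
                "offset": self.offsets,
                "mean": self.mean,
                "sem": self.sem,
            }
        )


def metaprofile(
    track: SignalTrack,
    sites: list[GenomicInterval],
    halfwidth: int = 1000,
    binsize: int = 20,
    chrom_sizes: dict[str, int] | None = None,
    assay: str = "",
    site_class: str = "",
) -> MetaProfile:
    """Mean per-base signal in bins across ±halfwidth around site centers.

    Sites whose window would be truncated by a chromosome end are
    dropped and counted. Without ``chrom_sizes`` the right boundary is
    taken from the track's covered extent per chromosome.
    """
    if not sites:
        raise ValueError("sites must be nonempty")
    if halfwidth % binsize != 0:
        raise ValueError("halfwidth must be divisible by binsize")
    nbins = 2 * halfwidth // binsize
    edges = np.arange(nbins + 1) * binsize - halfwidth

    rows = []
    dropped = 0
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.center)
    for chrom, centers in by_chrom.items():
        if chrom_sizes is not None:
            right = chrom_sizes.get(chrom, 0)
        else:
            ext = track.extent(chrom)
            right = ext[1] if ext else 0
        centers = np.asarray(centers, dtype=np.int64)
        ok = (centers - halfwidth >= 0) & (centers + halfwidth <= right)
        dropped += int((~ok).sum())
        centers = centers[ok]
        if len(centers) == 0:
            continue
        starts = centers[:, None] + edges[None, :-1]
        ends = centers[:, None] + edges[None, 1:]
        sums = track.batch_sum(
            chrom, starts.ravel(), ends.ravel()
        ).reshape(len(centers), nbins)
        rows.append(sums / binsize)
    if not rows:
        raise ValueError("all sites dropped (windows truncated)")
    mat = np.vstack(rows)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(nbins)
    )
    return MetaProfile(
        assay, site_class, halfwidth, binsize, mean, sem, n, dropped
    )


def class_shift_test(
    fold_changes_by_class: dict[str, np.ndarray]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise rank-sum comparisons of per-site fold-change distributions.

    Returns (pairwise table, cumulative-fraction curves per class).
    """
    names = list(fold_changes_by_class)
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(fold_changes_by_class[names[i]], dtype=np.float64)
            b = np.asarray(fold_changes_by_class[names[j]], dtype=np.float64)
            u, p, direction = rank_sum_shift(b, a)
            rows.append((names[i], names[j], len(a), len(b), u, p, direction))
    table = pd.DataFrame(
        rows,
        columns=["class_a", "class_b", "n_a", "n_b", "U", "p", "direction"],
    )
    return table, cumulative_curves(fold_changes_by_class)
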