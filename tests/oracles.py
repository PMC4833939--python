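"""Independent brute-force oracles shared by unit and acceptance tests.

Each function recomputes a pipeline quantity by naive per-base or
exhaustive enumeration, deliberately avoiding the package's vectorized
code paths.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def per_base_values(track, chrom: str, start: int, end: int) -> np.ndarray:
    """Expand a signal track to one value per base over [start, end)."""
    out = np.zeros(end - start)
    for c, s, e, v in track.iter_runs():
        if c != chrom:
            continue
        for pos in range(max(s, start), min(e, end)):
            out[pos - start] += v
    return out


def brute_overlap_count(set_a, set_b, min_overlap=1) -> int:
    """O(n*m) count of a-intervals overlapped by any b-interval."""
    n = 0
    for a in set_a:
        for b in set_b:
            if a.chrom == b.chrom and (
                min(a.end, b.end) - max(a.start, b.start) >= min_overlap
            ):
                n += 1
                break
    return n


def brute_pcr_filter(positions, counts, window=31, max_frac=0.70):
    """Sliding-window artifact filter by explicit window scans."""
    keep = []
    half = window // 2
    for p, c in zip(positions, counts):
        total = sum(
            c2 for p2, c2 in zip(positions, counts) if abs(p2 - p) <= half
        )
        if not (c > 0 and c / total > max_frac):
            keep.append((p, c))
    return keep


def brute_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios recomputed row by row with explicit loops."""
    ratios = [[] for _ in range(counts.shape[1])]
    for row in counts:
        if all(x > 0 for x in row):
            g = float(np.exp(np.mean([np.log(x) for x in row])))
            for j, x in enumerate(row):
                ratios[j].append(x / g)
    return np.array([float(np.median(r)) for r in ratios])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg from the definition (step-up, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def perm_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive-permutation two-sided Mann-Whitney p via rank sums.

    U is computed from the rank-sum identity (average ranks for ties),
    a different formula than the package's pairwise comparison count.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_of(mask):
        ranks = rankdata(pooled)
        r1 = ranks[mask].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs_mask = np.zeros(n1 + n2, dtype=bool)
    obs_mask[:n1] = True
    u_obs = u_of(obs_mask)
    mu = n1 * n2 / 2.0
    hits = 0
    for pick in combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(pick)] = True
        if abs(u_of(mask) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / comb(n1 + n2, n1)


def brute_tf_feature(track, site, halfwidth, window=200, step=100):
    """Max over sliding windows of mean per-base signal, per-base expansion."""
    center = (site.start + site.end) // 2
    best = -np.inf
    start = center - halfwidth
    while start + window <= center + halfwidth:
        vals = per_base_values(track, site.chrom, start, start + window)
        best = max(best, vals.mean())
        start += step
    return best


def brute_histone_feature(track, site, halfwidth=700):
    center = (site.start + site.end) // 2
    return per_base_values(
        track, site.chrom, center - halfwidth, center + halfwidth
    ).sum()
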