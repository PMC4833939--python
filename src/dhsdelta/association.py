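"""Association of accessibility changes with nearby expression changes.

Each DHS site is assigned to its single nearest gene (TSS-to-center
distance); genes are stratified by how many opened/closed sites they are
nearest to; each stratum's expression fold-change distribution is
compared against all expressed genes with a Mann-Whitney rank-sum test
and summarized as cumulative fraction curves.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneAnnotation, GenomicInterval

STRATA = ("ge1_opened", "ge1_closed", "ge2_opened", "ge2_closed")


def nearest_gene_map(
    sites: list[GenomicInterval], genes: list[GeneAnnotation]
) -> dict[str, str]:
    """site name -> gene_id of the gene whose TSS is nearest the site center.

    Ties break toward the smaller TSS coordinate, then lexicographic
    gene_id. Sites on chromosomes without genes are omitted.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    tss_sorted = {}
    for c, v in by_chrom.items():
        v.sort()
        tss_sorted[c] = (np.array([t for t, _ in v]), [gid for _, gid in v])
    out: dict[str, str] = {}
    for s in sites:
        entry = tss_sorted.get(s.chrom)
        if entry is None:
            continue
        coords, gids = entry
        center = s.center
        j = int(np.searchsorted(coords, center))
        best = None
        for i in (j - 1, j):
            if 0 <= i < len(coords):
                d = abs(int(coords[i]) - center)
                key = (d, int(coords[i]), gids[i])
                if best is None or key < best:
                    best = key
        out[s.name if s.name else f"{s.chrom}:{s.start}-{s.end}"] = best[2]
    return out


def stratify_genes(
    result: pd.DataFrame,
    site_gene_map: dict[str, str],
    universe: list[str] | set[str],
) -> dict[str, list[str]]:
    """Gene strata by counts of nearest opened/closed sites.

    ``universe`` is the expressed-gene background; strata are
    intersected with it. Returns background plus >=1 / >=2 opened and
    closed strata (each gene listed once per stratum).
    """
    universe = set(universe)
    counts: dict[str, dict[str, int]] = {}
    for row in result.itertuples(index=False):
        if row.status not in ("opened", "closed"):
            continue
        g = site_gene_map.get(row.site_id)
        if g is None or g not in universe:
            continue
        d = counts.setdefault(g, {"opened": 0, "closed": 0})
        d[row.status] += 1
    strata = {"background": sorted(universe)}
    for direction in ("opened", "closed"):
        for k in (1, 2):
            strata[f"ge{k}_{direction}"] = sorted(
                g for g, d in counts.items() if d[direction] >= k
            )
    return strata


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x relative to y, ties counted half."""
    gt = np.sum(x[:, None] > y[None, :])
    eq = np.sum(x[:, None] == y[None, :])
    return float(gt) + 0.5 * float(eq)


def _exact_perm_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive-permutation two-sided p for the U statistic.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes; the two-sided p is the fraction of assignments whose
    U lies at least as far from its permutation mean n1*n2/2 as observed.
    Correct in the presence of ties. Cost C(n1+n2, n1).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2.0
    u_obs = _u_statistic(x, y)
    d_obs = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    hits = 0
    idx_all = np.arange(n1 + n2)
    for pick in combinations(range(n1 + n2), n1):
        sel = np.zeros(n1 + n2, dtype=bool)
        sel[list(pick)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def rank_sum_shift(
    background: np.ndarray, stratum: np.ndarray, exact_limit: int = 12
) -> tuple[float, float, int]:
    """Two-sided Mann-Whitney test of a stratum against the background.

    Small layouts (n1 + n2 <= ``exact_limit``) use exhaustive
    permutation enumeration (exact even with ties); larger samples use
    the tie-corrected normal approximation. Returns (U, p, direction)
    where U is the stratum-vs-background statistic and direction the
    sign of the median difference.
    """
    x = np.asarray(stratum, dtype=np.float64)
    y = np.asarray(background, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    direction = int(np.sign(np.median(x) - np.median(y)))
    if len(x) + len(y) <= exact_limit:
        u, p = _exact_perm_p(x, y)
        return u, p, direction
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic")
    return float(u), float(p), direction


def cumulative_curves(
    values_by_stratum: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Empirical CDFs on the sorted union of observed values.

    Returns a long table (stratum, fc, cum_frac); each curve is monotone
    in [0, 1] and reaches exactly 1 at the largest grid point.
    """
    nonempty = {k: np.asarray(v, dtype=np.float64)
                for k, v in values_by_stratum.items() if len(v) > 0}
    if not nonempty:
        return pd.DataFrame(columns=["stratum", "fc", "cum_frac"])
    grid = np.unique(np.concatenate(list(nonempty.values())))
    frames = []
    for name, vals in nonempty.items():
        ecdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
        frames.append(
            pd.DataFrame({"stratum": name, "fc": grid, "cum_frac": ecdf})
        )
    return pd.concat(frames, ignore_index=True)


def associate(
    result: pd.DataFrame,
    expression: pd.DataFrame,
    genes: list[GeneAnnotation],
    sites: list[GenomicInterval],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Fig-2-style association: strata, rank-sum tests, CDF curves.

    Returns (association table, curves table). The association table has
    one row per stratum with n, U, p and the median shift relative to
    all expressed genes.
    """
    site_map = nearest_gene_map(sites, genes)
    fc = expression.set_index("gene_id")["log2fc"]
    strata = stratify_genes(result, site_map, list(fc.index))
    background = fc.loc[strata["background"]].to_numpy()
    rows = []
    values = {"background": background}
    for name in STRATA:
        members = strata[name]
        vals = fc.loc[members].to_numpy()
        values[name] = vals
        if len(vals) == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan))
            continue
        u, p, _ = rank_sum_shift(background, vals)
        rows.append(
            (name, len(vals), u, p,
             float(np.median(vals) - np.median(background)))
        )
    table = pd.DataFrame(
        rows, columns=["stratum", "n", "U", "p", "median_shift"]
    )
    return table, cumulative_curves(values)


def overlap_percentage(
    set_a: set[str] | list[str], set_b: set[str] | list[str]
) -> tuple[int, int, float]:
    """|A ∩ B|, |A|, and the percentage of A found in B (one decimal)."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set_a is empty; percentage undefined")
    inter = len(a & b)
    return inter, len(a), round(100.0 * inter / len(a), 1)
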