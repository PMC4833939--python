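"""Synthetic data with planted structure for every pipeline stage.

Emulates the statistical setting of an HDAC-inhibitor DNase-seq study:

* a small multi-chromosome genome with genes (TSS + exons) and
  non-overlapping DHS sites, a configurable fraction of which are
  promoter-proximal;
* negative-binomial replicate read counts with planted opened/closed
  sites (control vs treated);
* fragment-pileup signal tracks per assay with peak-shaped enrichment
  that differs by site class — a "poised" repressive-mark assay enriched
  at opened TF-bound sites, "active" marks/modifiers at stable bound
  sites, plus neutral assays with identical distributions across classes;
* a TF peak set covering the bound sites; and
* gene expression fold-changes coupled to nearby site opening, additive
  over direction-matched sites.

All randomness flows from one master seed; each generator draws from an
independent substream derived by hashing its name, so adding a generator
never shifts another's draws.
"""

from __future__ import annotations

import json
import zlib
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval, write_bed
from .signal import SignalTrack, write_bedgraph

STATUSES = ("opened", "closed", "stable")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    """Conditions the generator plants; defaults are the study-scale setting.

    ~10 % of sites are differential (half opened, half closed) at a
    planted |log2 fold-change| of 2, negative-binomial dispersion 0.05,
    3 replicates per condition, and ~20 % of sites promoter-proximal;
    after genic exclusion and covariate matching the default setting
    yields a matched classification set of roughly 930 rows.
    """

    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 8_000_000
    n_genes: int = 1200
    n_sites: int = 12_000
    site_width: int = 600
    n_reps: int = 3
    frac_open: float = 0.05
    frac_closed: float = 0.05
    frac_promoter: float = 0.20
    planted_lfc: float = 2.0
    dispersion: float = 0.05
    mean_log_mu: float = 4.6
    sd_log_mu: float = 1.0
    tf_bound_frac: float = 0.40
    poised_mark_effect: float = 3.0
    active_mark_effect: float = 3.0
    expr_coupling: float = 0.7
    expr_effect: float = 1.0
    expr_effect_sd: float = 0.5
    # track geometry
    bump_halfwidth: int = 500
    bump_resolution: int = 50
    background: float = 0.1
    # confound multipliers applied to DNase/TF bump amplitudes at opened
    # sites, so matched-control selection has real work to do
    dnase_confound: float = 2.0
    tf_confound: float = 2.0
    n_neutral_per_class: int = 3

    def __post_init__(self) -> None:
        for name in ("frac_open", "frac_closed", "frac_promoter",
                     "tf_bound_frac", "expr_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_open + self.frac_closed > 1.0:
            raise ValueError("frac_open + frac_closed must be <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.planted_lfc < 0:
            raise ValueError("planted_lfc must be >= 0")
        for name in ("n_chrom", "chrom_length", "n_genes", "n_reps",
                     "site_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class SimulationTruth:
    """Ground truth labels aligned with the simulated site list."""

    site_ids: list[str]
    status: np.ndarray  # 'opened' | 'closed' | 'stable' per site
    tf_bound: np.ndarray  # bool per site
    promoter: np.ndarray  # bool per site (planted promoter-proximal)
    gene_direction: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "status": self.status,
                "tf_bound": self.tf_bound,
                "promoter": self.promoter,
            }
        )


class PackingError(RuntimeError):
    pass


def _place_exons(
    rng: np.random.Generator, tss: int, strand: str, chrom: str, length: int
) -> list[GenomicInterval]:
    n_exons = int(rng.integers(2, 11))
    widths = rng.integers(100, 301, size=n_exons)
    gaps = rng.integers(200, 2001, size=n_exons - 1)
    coords = []
    pos = 0
    for i in range(n_exons):
        coords.append((pos, pos + int(widths[i])))
        pos += int(widths[i]) + (int(gaps[i]) if i < n_exons - 1 else 0)
    span = coords[-1][1]
    if strand == "+":
        offset = tss
        if offset + span > length:
            offset = length - span
        exons = [
            GenomicInterval(chrom, offset + s, offset + e) for s, e in coords
        ]
    else:
        offset = tss - span
        if offset < 0:
            offset = 0
        exons = [
            GenomicInterval(chrom, offset + s, offset + e) for s, e in coords
        ]
    return exons


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], list[GenomicInterval], SimulationTruth | None]:
    """Place genes and non-overlapping DHS sites on the synthetic genome.

    Returns (genes, sites, placement) where ``placement`` carries the
    planted promoter-proximal flag per site (other truth fields are
    filled in by :func:`simulate_counts` / :func:`simulate_tracks`).
    A ``frac_promoter`` fraction of site centers lie strictly within
    2 kb of a TSS; the remainder are at least 2 kb from every TSS and
    clear of all exons.
    """
    rng = substream(config.seed, "genome")
    L = config.chrom_length
    w = config.site_width
    if config.n_sites * w * 2 > config.n_chrom * L:
        raise PackingError(
            "genome too small for requested sites; increase chrom_length"
        )

    # genes: TSS away from chromosome edges so ±2 kb windows stay inside
    genes: list[GeneAnnotation] = []
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in config.chrom_names}
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {
        c: [] for c in config.chrom_names
    }
    margin = 60_000
    for g in range(config.n_genes):
        chrom = config.chrom_names[g % config.n_chrom]
        tss = int(rng.integers(margin, L - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _place_exons(rng, tss, strand, chrom, L)
        tss = exons[0].start if strand == "+" else exons[-1].end
        genes.append(GeneAnnotation(f"gene_{g:04d}", tss, strand, tuple(exons)))
        tss_by_chrom[chrom].append(tss)
        exons_by_chrom[chrom].extend((e.start, e.end) for e in exons)
    tss_sorted = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}
    exon_sorted = {
        c: sorted(v) for c, v in exons_by_chrom.items()
    }
    exon_starts = {
        c: np.array([s for s, _ in v]) for c, v in exon_sorted.items()
    }
    exon_ends = {
        c: np.array([e for _, e in v]) for c, v in exon_sorted.items()
    }

    def near_tss(chrom: str, center: int) -> bool:
        t = tss_sorted[chrom]
        if len(t) == 0:
            return False
        j = np.searchsorted(t, center)
        for i in (j - 1, j):
            if 0 <= i < len(t) and abs(int(t[i]) - center) < 2000:
                return True
        return False

    def hits_exon(chrom: str, start: int, end: int) -> bool:
        es, ee = exon_starts[chrom], exon_ends[chrom]
        if len(es) == 0:
            return False
        k = np.searchsorted(es, end, side="left")
        # exons are placed by independent genes and may interleave; scan a
        # bounded neighborhood (exons are < 301 bp, gaps bounded)
        lo = max(0, k - 64)
        return bool(np.any(ee[lo:k] > start))

    if config.n_sites == 0:
        return genes, [], None

    occupied: dict[str, list[tuple[int, int]]] = {
        c: [] for c in config.chrom_names
    }

    def free(chrom: str, start: int, end: int) -> bool:
        occ = occupied[chrom]
        j = bisect_left(occ, (start, start))
        for i in (j - 1, j):
            if 0 <= i < len(occ):
                s, e = occ[i]
                if s < end and start < e:
                    return False
        return True

    n_prom = int(round(config.frac_promoter * config.n_sites))
    want_promoter = np.zeros(config.n_sites, dtype=bool)
    want_promoter[rng.choice(config.n_sites, size=n_prom, replace=False)] = True

    records: list[tuple[str, int, int]] = []
    for i in range(config.n_sites):
        placed = False
        for _attempt in range(500):
            if want_promoter[i]:
                chrom = config.chrom_names[
                    int(rng.integers(0, config.n_chrom))
                ]
                t = tss_sorted[chrom]
                if len(t) == 0:
                    continue
                tss = int(t[int(rng.integers(0, len(t)))])
                center = tss + int(rng.integers(-1999, 2000))
                start = center - w // 2
                end = start + w
                if start < 0 or end > L:
                    continue
                ok = near_tss(chrom, (start + end) // 2)
            else:
                chrom = config.chrom_names[
                    int(rng.integers(0, config.n_chrom))
                ]
                start = int(rng.integers(0, L - w))
                end = start + w
                center = (start + end) // 2
                ok = not near_tss(chrom, center) and not hits_exon(
                    chrom, start, end
                )
            if ok and free(chrom, start, end):
                insort(occupied[chrom], (start, end))
                records.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise PackingError(
                "could not place all DHS sites; use longer chromosomes"
            )

    order = sorted(range(config.n_sites), key=lambda i: records[i])
    sites = []
    promoter_flags = np.zeros(config.n_sites, dtype=bool)
    for rank, i in enumerate(order):
        chrom, start, end = records[i]
        sites.append(
            GenomicInterval(chrom, start, end, name=f"site_{rank:05d}")
        )
        promoter_flags[rank] = want_promoter[i]
    placement = SimulationTruth(
        site_ids=[s.name for s in sites],
        status=np.full(config.n_sites, "stable", dtype=object),
        tf_bound=np.zeros(config.n_sites, dtype=bool),
        promoter=promoter_flags,
    )
    return genes, sites, placement


# --- counts ---------------------------------------------------------------


@dataclass
class DhsCountMatrix:
    """Raw DHS read counts, sites x samples, with condition labels."""

    sites: list[GenomicInterval]
    counts: np.ndarray  # (n_sites, n_samples) non-negative ints
    sample_condition: list[str]  # 'control' | 'treated'
    sample_replicate: list[int]

    def __post_init__(self) -> None:
        n, m = self.counts.shape
        if n != len(self.sites) or m != len(self.sample_condition):
            raise ValueError("count matrix dimensions inconsistent")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{c}_{r}"
            for c, r in zip(self.sample_condition, self.sample_replicate)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=self.sample_names, dtype=np.int64
        )
        df.insert(0, "site_id", [s.name for s in self.sites])
        return df


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean, var = mean + alpha * mean^2); Poisson limit at alpha ~ 0."""
    mean = np.asarray(mean, dtype=np.float64)
    if alpha < 1e-9:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    sites: list[GenomicInterval],
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
) -> tuple[DhsCountMatrix, SimulationTruth]:
    """Draw replicate NB counts with planted opened/closed sites.

    Baseline site means are log-normal; treated means are scaled by
    2**(+/- planted_lfc) for opened/closed sites; per-sample size
    factors are uniform in [0.7, 1.4].
    """
    if not sites:
        raise ValueError("sites must be nonempty")
    rng = substream(config.seed, "counts")
    n = len(sites)
    if truth is None:
        truth = SimulationTruth(
            site_ids=[s.name for s in sites],
            status=np.full(n, "stable", dtype=object),
            tf_bound=np.zeros(n, dtype=bool),
            promoter=np.zeros(n, dtype=bool),
        )
    n_open = int(round(config.frac_open * n))
    n_closed = int(round(config.frac_closed * n))
    perm = rng.permutation(n)
    status = np.full(n, "stable", dtype=object)
    status[perm[:n_open]] = "opened"
    status[perm[n_open:n_open + n_closed]] = "closed"
    truth.status = status

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n)
    lfc = np.zeros(n)
    lfc[status == "opened"] = config.planted_lfc
    lfc[status == "closed"] = -config.planted_lfc
    mu_treated = mu * 2.0**lfc

    n_samples = 2 * config.n_reps
    size_factors = rng.uniform(0.7, 1.4, size=n_samples)
    counts = np.empty((n, n_samples), dtype=np.int64)
    conditions, replicates = [], []
    for j in range(n_samples):
        treated = j >= config.n_reps
        conditions.append("treated" if treated else "control")
        replicates.append(j % config.n_reps + 1)
        m = (mu_treated if treated else mu) * size_factors[j]
        counts[:, j] = _nb_draw(rng, m, config.dispersion)
    matrix = DhsCountMatrix(sites, counts, conditions, replicates)
    return matrix, truth


# --- signal tracks --------------------------------------------------------


def assay_panel(config: SimulationConfig) -> pd.DataFrame:
    """The manifest of simulated assays: name, feature class, planted role.

    Roles: ``poised`` (enriched at opened & bound sites), ``active``
    (enriched at stable & bound sites), ``neutral`` (no class effect).
    The DNase and focal-TF tracks serve matching/profiles, not the
    feature panel.
    """
    rows = [
        ("dnase", "histone_mod", "matching"),
        ("tf_focal", "tf", "tf"),
        ("poised_mark", "histone_mod", "poised"),
        ("active_mark", "histone_mod", "active"),
        ("active_modifier", "chromatin_modifier", "active"),
    ]
    for k in range(config.n_neutral_per_class):
        rows.append((f"neutral_tf_{k + 1}", "tf", "neutral"))
        rows.append((f"neutral_histone_{k + 1}", "histone_mod", "neutral"))
        rows.append((f"neutral_modifier_{k + 1}", "chromatin_modifier",
                     "neutral"))
    return pd.DataFrame(rows, columns=["assay", "feature_class", "role"])


def bumps_track(
    chrom_sizes: dict[str, int],
    chroms: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    halfwidth: int = 500,
    resolution: int = 50,
    background: float = 0.1,
) -> SignalTrack:
    """Render triangular peak-shaped bumps onto a constant background.

    The genome is discretized at ``resolution`` bp; overlapping bumps
    add. Used by the generator and by focused test constructions.
    """
    arrays = {}
    for chrom, L in chrom_sizes.items():
        nbin = int(np.ceil(L / resolution))
        grid = np.full(nbin, float(background))
        sel = chroms == chrom
        if np.any(sel):
            cs = centers[sel].astype(np.int64)
            amps = amplitudes[sel].astype(np.float64)
            nb = 2 * halfwidth // resolution
            offs = (np.arange(nb) - nb / 2 + 0.5) * resolution
            for c, a in zip(cs, amps):
                b0 = c // resolution - nb // 2
                idx = np.arange(b0, b0 + nb)
                good = (idx >= 0) & (idx < nbin)
                shape = np.clip(1.0 - np.abs(offs) / halfwidth, 0.0, None)
                np.add.at(grid, idx[good], a * shape[good])
        # compress equal-valued neighbours into runs
        change = np.flatnonzero(np.diff(grid)) + 1
        run_starts = np.concatenate(([0], change))
        run_ends = np.concatenate((change, [nbin]))
        starts = run_starts * resolution
        ends = np.minimum(run_ends * resolution, L)
        values = grid[run_starts]
        keep = values > 0
        arrays[chrom] = (starts[keep], ends[keep], values[keep])
    track = SignalTrack.from_arrays(arrays)
    track.mapped_reads = max(1, int(round(track.total_signal / 200.0)))
    return track


def simulate_tracks(
    sites: list[GenomicInterval],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[dict[str, SignalTrack], list[GenomicInterval]]:
    """Per-assay pileup tracks plus the focal-TF peak set.

    DNase and focal-TF amplitudes are inflated at opened sites (the
    planted confound that matching must remove); the poised mark is
    multiplied by ``poised_mark_effect`` at opened & TF-bound sites and
    the active mark/modifier by ``active_mark_effect`` at stable &
    bound sites. Neutral assays have the same amplitude law everywhere.
    """
    rng = substream(config.seed, "tracks")
    n = len(sites)
    chroms = np.array([s.chrom for s in sites])
    centers = np.array([s.center for s in sites], dtype=np.int64)
    truth.tf_bound = rng.random(n) < config.tf_bound_frac
    opened = truth.status == "opened"
    stable = truth.status == "stable"
    bound = truth.tf_bound

    sizes = config.chrom_sizes

    def render(amps: np.ndarray) -> SignalTrack:
        return bumps_track(
            sizes, chroms, centers, amps,
            halfwidth=config.bump_halfwidth,
            resolution=config.bump_resolution,
            background=config.background,
        )

    tracks: dict[str, SignalTrack] = {}

    # shared per-site activity couples accessibility and TF occupancy,
    # as in real data where stronger DHS sites carry more TF signal
    activity = rng.lognormal(0.0, 0.5, size=n)

    amp = activity * rng.lognormal(np.log(5.0), 0.4, size=n)
    amp[opened] *= config.dnase_confound
    tracks["dnase"] = render(amp)

    amp = activity * np.where(
        bound,
        rng.lognormal(np.log(8.0), 0.35, size=n),
        rng.lognormal(np.log(2.0), 0.35, size=n),
    )
    amp[opened] *= config.tf_confound
    tracks["tf_focal"] = render(amp)

    amp = rng.lognormal(np.log(4.0), 0.5, size=n)
    amp[opened & bound] *= config.poised_mark_effect
    tracks["poised_mark"] = render(amp)

    for name in ("active_mark", "active_modifier"):
        amp = rng.lognormal(np.log(4.0), 0.5, size=n)
        amp[stable & bound] *= config.active_mark_effect
        tracks[name] = render(amp)

    panel = assay_panel(config)
    for name in panel.loc[panel.role == "neutral", "assay"]:
        amp = rng.lognormal(np.log(4.0), 0.5, size=n)
        tracks[name] = render(amp)

    tf_peaks = [
        GenomicInterval(s.chrom, s.center - 200, s.center + 200,
                        name=f"peak_{i:05d}")
        for i, s in enumerate(sites)
        if bound[i]
    ]
    return tracks, tf_peaks


# --- expression -----------------------------------------------------------


def simulate_expression(
    genes: list[GeneAnnotation],
    sites: list[GenomicInterval],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Gene expression fold-changes coupled to nearby site status.

    Each opened (closed) site contributes, with probability
    ``expr_coupling``, an independent Normal(+effect, sd)
    (Normal(-effect, sd)) increment to the log2 fold-change of its
    nearest gene; increments add over sites. Genes with no planted
    increment draw Normal(0, sd). Planted genes get fdr < 0.05.
    """
    from .association import nearest_gene_map

    rng = substream(config.seed, "expression")
    gene_ids = [g.gene_id for g in genes]
    idx = {g: i for i, g in enumerate(gene_ids)}
    site_to_gene = nearest_gene_map(sites, genes)
    effects = np.zeros(len(genes))
    planted = np.zeros(len(genes), dtype=bool)
    for i, s in enumerate(sites):
        st = truth.status[i]
        if st == "stable":
            continue
        g = site_to_gene.get(s.name)
        if g is None:
            continue
        if rng.random() < config.expr_coupling:
            sign = 1.0 if st == "opened" else -1.0
            effects[idx[g]] += rng.normal(
                sign * config.expr_effect, config.expr_effect_sd
            )
            planted[idx[g]] = True
    noise = rng.normal(0.0, config.expr_effect_sd, size=len(genes))
    log2fc = np.where(planted, effects, noise)
    fdr = np.where(
        planted,
        rng.uniform(0.001, 0.049, size=len(genes)),
        rng.uniform(0.05, 1.0, size=len(genes)),
    )
    truth.gene_direction = {
        g: int(np.sign(effects[idx[g]])) if planted[idx[g]] else 0
        for g in gene_ids
    }
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": log2fc, "fdr": fdr}
    )


# --- dataset bundle -------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneAnnotation]
    sites: list[GenomicInterval]
    truth: SimulationTruth
    counts: DhsCountMatrix
    tracks: dict[str, SignalTrack]
    tf_peaks: list[GenomicInterval]
    expression: pd.DataFrame
    assays: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage under one master seed."""
    genes, sites, placement = simulate_genome(config)
    counts, truth = simulate_counts(sites, config, placement)
    tracks, tf_peaks = simulate_tracks(sites, truth, config)
    expression = simulate_expression(genes, sites, truth, config)
    return SimulatedDataset(
        config, genes, sites, truth, counts, tracks, tf_peaks, expression,
        assay_panel(config),
    )


def genes_to_frame(genes: list[GeneAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "exon_starts": [
                ",".join(str(e.start) for e in g.exons) for g in genes
            ],
            "exon_ends": [
                ",".join(str(e.end) for e in g.exons) for g in genes
            ],
        }
    )


def genes_from_frame(df: pd.DataFrame) -> list[GeneAnnotation]:
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        exons = tuple(
            GenomicInterval(row.chrom, s, e) for s, e in zip(starts, ends)
        )
        genes.append(GeneAnnotation(row.gene_id, int(row.tss), row.strand,
                                    exons))
    return genes


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every artifact as plain text under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sites"] = outdir / "sites.bed"
    write_bed(ds.sites, paths["sites"])
    paths["tf_peaks"] = outdir / "tf_peaks.bed"
    write_bed(ds.tf_peaks, paths["tf_peaks"])
    paths["counts"] = outdir / "counts.tsv"
    ds.counts.to_frame().to_csv(paths["counts"], sep="\t", index=False)
    paths["samples"] = outdir / "samples.tsv"
    pd.DataFrame(
        {
            "sample": ds.counts.sample_names,
            "condition": ds.counts.sample_condition,
            "replicate": ds.counts.sample_replicate,
        }
    ).to_csv(paths["samples"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    ds.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"
    ds.expression.to_csv(paths["expression"], sep="\t", index=False)
    paths["genes"] = outdir / "genes.tsv"
    genes_to_frame(ds.genes).to_csv(paths["genes"], sep="\t", index=False)
    for name, track in ds.tracks.items():
        p = outdir / f"{name}.bedGraph"
        write_bedgraph(track, p)
        paths[f"track:{name}"] = p
    paths["assays"] = outdir / "assays.tsv"
    manifest = ds.assays.copy()
    manifest["path"] = [
        str(outdir / f"{a}.bedGraph") for a in manifest["assay"]
    ]
    manifest["mapped_reads"] = [
        ds.tracks[a].mapped_reads for a in manifest["assay"]
    ]
    manifest.to_csv(paths["assays"], sep="\t", index=False)
    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(asdict(ds.config), fh, indent=2)
    return paths
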