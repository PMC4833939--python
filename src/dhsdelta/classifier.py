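"""Matched random-forest classification of opened versus stable DHS sites.

Procedure: drop genic sites (promoter-proximal or exon-overlapping);
pair each opened site with an unused stable site of close-to-equal
baseline DNase and focal-TF signal (greedy seeded nearest-neighbor in
standardized covariate space, caliper-bounded); extract windowed signal
features per assay class; train a random forest over repeated stratified
75/25 splits; rank features by Gini importance with permutation
importance as tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    nearest_coordinate,
    overlapping_mask,
)
from .signal import SignalTrack
from .simulate import substream

FEATURE_CLASSES = ("tf", "chromatin_modifier", "histone_mod")


def exclude_genic(
    sites: list[GenomicInterval],
    genes: list[GeneAnnotation],
    tss_threshold: int = 2000,
) -> list[GenomicInterval]:
    """Drop sites whose center is within ``tss_threshold`` of a TSS or
    whose interval overlaps any exon."""
    tss_by_chrom: dict[str, list[int]] = {}
    exons: list[GenomicInterval] = []
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        exons.extend(g.exons)
    tss_by_chrom = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}
    exonic = overlapping_mask(sites, exons) if exons else np.zeros(
        len(sites), dtype=bool
    )
    kept = []
    for i, s in enumerate(sites):
        if exonic[i]:
            continue
        t = tss_by_chrom.get(s.chrom)
        if t is not None and len(t):
            _, d = nearest_coordinate(t, s.center)
            if d < tss_threshold:
                continue
        kept.append(s)
    return kept


@dataclass
class MatchedSiteSet:
    """1:1 opened/stable pairs matched on baseline covariates."""

    opened: list[GenomicInterval]
    stable: list[GenomicInterval]
    pair_distances: np.ndarray
    caliper: float
    n_dropped: int
    # standardized covariates of the full candidate pools, for diagnostics
    covariates_opened: np.ndarray = field(repr=False, default=None)
    covariates_stable: np.ndarray = field(repr=False, default=None)
    matched_opened_idx: np.ndarray = field(repr=False, default=None)
    matched_stable_idx: np.ndarray = field(repr=False, default=None)


def _matching_covariates(
    sites: list[GenomicInterval],
    dnase_track: SignalTrack,
    tf_track: SignalTrack,
    dnase_halfwidth: int = 200,
    tf_halfwidth: int = 150,
) -> np.ndarray:
    """log1p summed signal in center±200 (DNase) and center±150 (TF)."""
    def windows(hw: int) -> list[GenomicInterval]:
        return [
            GenomicInterval(s.chrom, s.center - hw, s.center + hw)
            for s in sites
        ]

    dn = np.log1p(dnase_track.interval_sums(windows(dnase_halfwidth)))
    tf = np.log1p(tf_track.interval_sums(windows(tf_halfwidth)))
    return np.column_stack([dn, tf])


def standardized_mean_difference(
    x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-column SMD: (mean(x) - mean(y)) / pooled SD."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    sd = np.sqrt(
        (np.var(x, axis=0, ddof=1) + np.var(y, axis=0, ddof=1)) / 2.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, (x.mean(axis=0) - y.mean(axis=0)) / sd, 0.0)


def match_controls(
    opened: list[GenomicInterval],
    stable: list[GenomicInterval],
    dnase_track: SignalTrack,
    tf_track: SignalTrack,
    caliper: float = 0.25,
    seed: int = 0,
) -> MatchedSiteSet:
    """Greedy seeded 1:1 nearest-neighbor matching without replacement.

    Covariates are log1p summed DNase (center±200 bp) and focal-TF
    (center±150 bp) signal, standardized over the pooled opened+stable
    set. Opened sites are processed in random order; each takes its
    Euclidean-nearest unused stable site if within ``caliper``
    (standardized units), else is dropped.
    """
    if not opened or not stable:
        raise ValueError("both opened and stable site lists must be nonempty")
    cov = _matching_covariates(opened + stable, dnase_track, tf_track)
    mu = cov.mean(axis=0)
    sd = cov.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    cov = (cov - mu) / sd
    cov_o = cov[: len(opened)]
    cov_s = cov[len(opened):]

    rng = substream(seed, "matching")
    order = rng.permutation(len(opened))
    used = np.zeros(len(stable), dtype=bool)
    pairs_o, pairs_s, dists = [], [], []
    for i in order:
        d = np.linalg.norm(cov_s - cov_o[i], axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper:
            used[j] = True
            pairs_o.append(int(i))
            pairs_s.append(j)
            dists.append(float(d[j]))
    if not pairs_o:
        raise ValueError(
            "no matches within caliper; covariate summary — opened mean "
            f"{cov_o.mean(axis=0)}, stable mean {cov_s.mean(axis=0)}"
        )
    # restore deterministic output order by opened index
    key = np.argsort(pairs_o)
    pairs_o = [pairs_o[k] for k in key]
    pairs_s = [pairs_s[k] for k in key]
    dists = np.array([dists[k] for k in key])
    return MatchedSiteSet(
        opened=[opened[i] for i in pairs_o],
        stable=[stable[j] for j in pairs_s],
        pair_distances=dists,
        caliper=caliper,
        n_dropped=len(opened) - len(pairs_o),
        covariates_opened=cov_o,
        covariates_stable=cov_s,
        matched_opened_idx=np.array(pairs_o),
        matched_stable_idx=np.array(pairs_s),
    )


def covariate_balance(mset: MatchedSiteSet) -> pd.DataFrame:
    """Pre- and post-match SMD per matching covariate."""
    pre = standardized_mean_difference(
        mset.covariates_opened, mset.covariates_stable
    )
    post = standardized_mean_difference(
        mset.covariates_opened[mset.matched_opened_idx],
        mset.covariates_stable[mset.matched_stable_idx],
    )
    return pd.DataFrame(
        {
            "covariate": ["dnase_log1p_sum", "tf_log1p_sum"],
            "smd_pre": pre,
            "smd_post": post,
        }
    )


@dataclass(frozen=True)
class FeatureSpec:
    """How one assay becomes one feature column.

    ``tf``: max over sliding 200-bp windows (100-bp step) of the mean
    per-base signal within center±300 bp. ``chromatin_modifier``: the
    same statistic over center±700 bp. ``histone_mod``: total summed
    signal in center±700 bp.
    """

    assay: str
    feature_class: str
    window: int = 200
    step: int = 100

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.window % self.step != 0:
            raise ValueError("step must divide window length")

    @property
    def halfwidth(self) -> int:
        return 300 if self.feature_class == "tf" else 700

    @property
    def statistic(self) -> str:
        return "sum" if self.feature_class == "histone_mod" else "window_max"


@dataclass
class FeatureMatrix:
    """Matched sites x feature columns, with opened/stable labels."""

    data: pd.DataFrame  # one column per feature
    labels: np.ndarray  # 'opened' | 'stable'
    site_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValueError("labels must align with rows")
        if self.data.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")


def _window_max_means(
    track: SignalTrack, sites: list[GenomicInterval], halfwidth: int,
    window: int, step: int,
) -> np.ndarray:
    """Max over edge-anchored sliding windows of the window mean signal."""
    n_win = (2 * halfwidth - window) // step + 1
    offsets = np.arange(n_win) * step - halfwidth
    out = np.zeros(len(sites))
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        centers = np.array([sites[i].center for i in idx], dtype=np.int64)
        starts = centers[:, None] + offsets[None, :]
        sums = track.batch_sum(
            chrom, starts.ravel(), (starts + window).ravel()
        ).reshape(len(idx), n_win)
        out[idx] = sums.max(axis=1) / window
    return out


def extract_features(
    matched: MatchedSiteSet,
    tracks: dict[str, SignalTrack],
    specs: list[FeatureSpec],
) -> FeatureMatrix:
    """Windowed signal features for the matched opened+stable rows."""
    sites = matched.opened + matched.stable
    labels = np.array(
        ["opened"] * len(matched.opened) + ["stable"] * len(matched.stable),
        dtype=object,
    )
    cols = {}
    for spec in specs:
        track = tracks.get(spec.assay)
        if track is None:
            raise KeyError(f"no signal track supplied for assay {spec.assay!r}")
        if spec.statistic == "sum":
            windows = [
                GenomicInterval(
                    s.chrom, s.center - spec.halfwidth,
                    s.center + spec.halfwidth,
                )
                for s in sites
            ]
            cols[spec.assay] = track.interval_sums(windows)
        else:
            cols[spec.assay] = _window_max_means(
                track, sites, spec.halfwidth, spec.window, spec.step
            )
    site_ids = [
        s.name if s.name else f"{s.chrom}:{s.start}-{s.end}" for s in sites
    ]
    return FeatureMatrix(pd.DataFrame(cols), labels, site_ids)


@dataclass
class ClassifierReport:
    runs: pd.DataFrame  # per-run accuracy / sensitivity / specificity
    gini_importance: pd.DataFrame  # per feature x run
    permutation_importance: pd.DataFrame  # per feature x run
    feature_names: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(self.runs["accuracy"].mean())


def train_eval(
    features: FeatureMatrix,
    n_runs: int = 10,
    train_frac: float = 0.75,
    n_trees: int = 500,
    mtry: int = 10,
    seed: int = 0,
    n_perm: int = 3,
) -> ClassifierReport:
    """Repeated stratified-split random-forest evaluation.

    Per run: a stratified ``train_frac`` split, a forest with ``n_trees``
    trees and ``mtry`` features per split, held-out accuracy,
    sensitivity (recall of 'opened') and specificity (recall of
    'stable'), Gini importances, and permutation importances (mean
    decrease in held-out accuracy over ``n_perm`` column shuffles).
    """
    X = features.data.to_numpy(dtype=np.float64)
    y = (features.labels == "opened").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both opened and stable rows")
    if mtry > X.shape[1]:
        raise ValueError(
            f"mtry={mtry} exceeds the number of features ({X.shape[1]})"
        )
    rng = substream(seed, "train_eval")
    run_rows, gini_rows, perm_rows = [], [], []
    for run in range(n_runs):
        rs = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=rs
        )
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=rs,
            n_jobs=1,
        )
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        acc = accuracy_score(y_te, pred)
        sens = float(np.mean(pred[y_te == 1] == 1)) if np.any(y_te == 1) else np.nan
        spec = float(np.mean(pred[y_te == 0] == 0)) if np.any(y_te == 0) else np.nan
        run_rows.append((run, acc, sens, spec))
        gini_rows.append(clf.feature_importances_)
        drops = np.zeros(X.shape[1])
        perm_rng = np.random.default_rng(rs)
        for k in range(X.shape[1]):
            accs = []
            for _ in range(n_perm):
                Xp = X_te.copy()
                Xp[:, k] = perm_rng.permutation(Xp[:, k])
                accs.append(accuracy_score(y_te, clf.predict(Xp)))
            drops[k] = acc - float(np.mean(accs))
        perm_rows.append(drops)
    runs = pd.DataFrame(
        run_rows, columns=["run", "accuracy", "sensitivity", "specificity"]
    )
    names = list(features.data.columns)
    gini = pd.DataFrame(gini_rows, columns=names)
    perm = pd.DataFrame(perm_rows, columns=names)
    return ClassifierReport(runs, gini, perm, names)


def rank_features(report: ClassifierReport, top_k: int = 15) -> pd.DataFrame:
    """Features sorted by mean Gini importance (ties: permutation
    importance, then name), with per-run rank variance as stability."""
    gini_mean = report.gini_importance.mean(axis=0)
    perm_mean = report.permutation_importance.mean(axis=0)
    per_run_rank = report.gini_importance.rank(
        axis=1, ascending=False, method="average"
    )
    table = pd.DataFrame(
        {
            "feature": report.feature_names,
            "gini_importance": gini_mean.to_numpy(),
            "permutation_importance": perm_mean.to_numpy(),
            "rank_variance": per_run_rank.var(axis=0, ddof=0).to_numpy(),
        }
    )
    table = table.sort_values(
        by=["gini_importance", "permutation_importance", "feature"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.head(top_k)
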