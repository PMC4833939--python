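import numpy as np
import pandas as pd
import pytest

import dhsdelta as dd
from dhsdelta.classifier import (
    FeatureMatrix,
    FeatureSpec,
    covariate_balance,
    exclude_genic,
    extract_features,
    match_controls,
    rank_features,
    train_eval,
)
from dhsdelta.simulate import bumps_track
from conftest import random_track
from oracles import brute_histone_feature, brute_tf_feature


def gene_with_exon(tss, chrom="chr1"):
    return dd.GeneAnnotation(
        f"g{tss}", tss, "+",
        (dd.GenomicInterval(chrom, tss, tss + 250),
         dd.GenomicInterval(chrom, tss + 1000, tss + 1300)),
    )


class TestExcludeGenic:
    def test_exonic_site_removed(self):
        genes = [gene_with_exon(100_000)]
        inside_exon = dd.GenomicInterval("chr1", 100_900, 101_500)
        assert exclude_genic([inside_exon], genes) == []

    def test_distal_intergenic_site_retained(self):
        genes = [gene_with_exon(100_000)]
        distal = dd.GenomicInterval("chr1", 200_000, 200_600)
        assert exclude_genic([distal], genes) == [distal]

    def test_promoter_proximal_site_removed(self):
        genes = [gene_with_exon(100_000)]
        near = dd.GenomicInterval("chr1", 98_200, 98_800)  # center 98.5 kb
        assert exclude_genic([near], genes) == []

    def test_generator_truth_recovered(self, small_dataset):
        ds = small_dataset
        kept = exclude_genic(ds.sites, ds.genes)
        expected = {
            sid for sid, prom in zip(ds.truth.site_ids, ds.truth.promoter)
            if not prom
        }
        assert {s.name for s in kept} == expected


def confounded_sets(seed=0, n_open=150, n_stable=1200, shift=2.0):
    """Opened/stable site sets whose DNase/TF amplitudes are confounded."""
    rng = np.random.default_rng(seed)
    n = n_open + n_stable
    starts = np.arange(n) * 2500 + 1000
    sites = [
        dd.GenomicInterval("chr1", int(s), int(s) + 600, name=f"c{i:04d}")
        for i, s in enumerate(starts)
    ]
    sizes = {"chr1": int(starts[-1] + 5000)}
    chroms = np.array(["chr1"] * n)
    centers = np.array([s.center for s in sites])
    amps_d = rng.lognormal(np.log(5.0), 0.6, size=n)
    amps_t = rng.lognormal(np.log(5.0), 0.6, size=n)
    amps_d[:n_open] *= shift
    amps_t[:n_open] *= shift
    dnase = bumps_track(sizes, chroms, centers, amps_d)
    tf = bumps_track(sizes, chroms, centers, amps_t)
    return sites[:n_open], sites[n_open:], dnase, tf


class TestMatchControls:
    def test_identical_pools_match_perfectly(self):
        opened, stable, dnase, tf = confounded_sets(shift=1.0)
        # use the same covariates by matching opened against itself via
        # duplicated stable sites at identical coordinates is impossible;
        # instead check zero distances when pools coincide statistically
        mset = match_controls(opened, opened, dnase, tf, seed=1)
        assert mset.n_dropped == 0
        assert np.allclose(mset.pair_distances, 0.0)

    def test_no_reuse_and_caliper_respected(self):
        opened, stable, dnase, tf = confounded_sets()
        mset = match_controls(opened, stable, dnase, tf, seed=2)
        names = [s.name for s in mset.stable]
        assert len(names) == len(set(names))
        assert (mset.pair_distances <= mset.caliper + 1e-12).all()

    def test_degenerate_caliper_with_disjoint_covariates_raises(self):
        opened, stable, dnase, tf = confounded_sets(shift=50.0)
        with pytest.raises(ValueError, match="caliper"):
            match_controls(opened, stable, dnase, tf, caliper=1e-9, seed=3)

    def test_balance_diagnostic_on_confounded_sets(self):
        opened, stable, dnase, tf = confounded_sets()
        mset = match_controls(opened, stable, dnase, tf, seed=4)
        balance = covariate_balance(mset)
        assert (balance["smd_pre"].abs() > 0.5).all()
        assert (balance["smd_post"].abs() < 0.1).all()

    def test_deterministic_given_seed(self):
        opened, stable, dnase, tf = confounded_sets()
        m1 = match_controls(opened, stable, dnase, tf, seed=5)
        m2 = match_controls(opened, stable, dnase, tf, seed=5)
        assert [s.name for s in m1.stable] == [s.name for s in m2.stable]


def trivial_matched(sites_a, sites_b):
    return dd.MatchedSiteSet(
        opened=sites_a, stable=sites_b,
        pair_distances=np.zeros(len(sites_a)), caliper=0.25, n_dropped=0,
    )


class TestExtractFeatures:
    def test_constant_track_features(self):
        track = dd.SignalTrack([("chr1", 0, 100_000, 2.0)])
        site = dd.GenomicInterval("chr1", 50_000, 50_600, name="a")
        other = dd.GenomicInterval("chr1", 30_000, 30_600, name="b")
        fm = extract_features(
            trivial_matched([site], [other]),
            {"x": track, "h": track},
            [FeatureSpec("x", "tf"), FeatureSpec("h", "histone_mod")],
        )
        assert fm.data.loc[0, "x"] == pytest.approx(2.0)
        assert fm.data.loc[0, "h"] == pytest.approx(2.0 * 1400)

    def test_single_window_bump_max_semantics(self):
        # 200-bp plateau of height 7 aligned with the first tf window
        center = 50_000
        track = dd.SignalTrack(
            [("chr1", center - 300, center - 100, 7.0)]
        )
        site = dd.GenomicInterval("chr1", center - 300, center + 300,
                                  name="a")
        fm = extract_features(
            trivial_matched([site], [site]), {"x": track},
            [FeatureSpec("x", "tf")],
        )
        assert fm.data.loc[0, "x"] == pytest.approx(7.0)

    def test_missing_track_names_assay(self):
        site = dd.GenomicInterval("chr1", 0, 600, name="a")
        with pytest.raises(KeyError, match="absent_assay"):
            extract_features(
                trivial_matched([site], [site]), {},
                [FeatureSpec("absent_assay", "tf")],
            )

    @pytest.mark.parametrize(
        "feature_class", ["tf", "chromatin_modifier", "histone_mod"]
    )
    def test_matches_per_base_oracle(self, rng, feature_class):
        track = random_track(rng, span=40_000, n_runs=300, max_gap=80)
        sites = [
            dd.GenomicInterval(
                "chr1", int(c), int(c) + 600, name=f"s{i}"
            )
            for i, c in enumerate(rng.integers(2000, 20_000, size=25))
        ]
        spec = FeatureSpec("x", feature_class)
        fm = extract_features(
            trivial_matched(sites[:12], sites[12:24]), {"x": track}, [spec]
        )
        for row, site in enumerate(sites[:12] + sites[12:24]):
            if feature_class == "histone_mod":
                expected = brute_histone_feature(track, site)
            else:
                expected = brute_tf_feature(track, site, spec.halfwidth)
            assert fm.data.loc[row, "x"] == pytest.approx(expected, abs=1e-9)


def planted_feature_matrix(seed=0, n_rows=200, n_noise=20, disjoint=True):
    rng = np.random.default_rng(seed)
    labels = np.array(
        ["opened"] * (n_rows // 2) + ["stable"] * (n_rows // 2), dtype=object
    )
    data = pd.DataFrame(
        rng.normal(size=(n_rows, n_noise)),
        columns=[f"noise_{i:02d}" for i in range(n_noise)],
    )
    if disjoint:
        data["planted"] = np.where(
            labels == "opened",
            rng.uniform(2, 3, size=n_rows),
            rng.uniform(0, 1, size=n_rows),
        )
    return FeatureMatrix(data, labels, [f"r{i}" for i in range(n_rows)])


class TestTrainEval:
    def test_null_labels_give_chance_accuracy(self):
        fm = planted_feature_matrix(seed=1, disjoint=False)
        rng = np.random.default_rng(7)
        shuffled = fm.labels.copy()
        rng.shuffle(shuffled)
        report = train_eval(
            FeatureMatrix(fm.data, shuffled, fm.site_ids),
            n_trees=200, mtry=5, seed=1,
        )
        assert abs(report.mean_accuracy - 0.5) <= 0.1

    def test_planted_feature_recovered(self):
        fm = planted_feature_matrix(seed=2)
        report = train_eval(fm, seed=2)
        assert report.mean_accuracy >= 0.95
        ranks = report.gini_importance.rank(axis=1, ascending=False)
        assert (ranks["planted"] == 1).sum() >= 9

    def test_deterministic_given_seed(self):
        fm = planted_feature_matrix(seed=3)
        r1 = train_eval(fm, n_runs=2, n_trees=50, mtry=5, seed=9)
        r2 = train_eval(fm, n_runs=2, n_trees=50, mtry=5, seed=9)
        pd.testing.assert_frame_equal(r1.runs, r2.runs)
        pd.testing.assert_frame_equal(r1.gini_importance, r2.gini_importance)
        pd.testing.assert_frame_equal(
            r1.permutation_importance, r2.permutation_importance
        )

    def test_mtry_exceeding_features_raises(self):
        fm = planted_feature_matrix(seed=4, n_noise=3)
        with pytest.raises(ValueError, match="mtry"):
            train_eval(fm, mtry=50)

    def test_single_class_raises(self):
        fm = planted_feature_matrix(seed=5)
        labels = np.array(["opened"] * len(fm.labels), dtype=object)
        with pytest.raises(ValueError):
            train_eval(FeatureMatrix(fm.data, labels, fm.site_ids))


class TestRankFeatures:
    def test_single_feature_is_rank_one(self):
        rng = np.random.default_rng(0)
        labels = np.array(["opened"] * 30 + ["stable"] * 30, dtype=object)
        data = pd.DataFrame({"only": rng.normal(size=60)})
        fm = FeatureMatrix(data, labels, [f"r{i}" for i in range(60)])
        report = train_eval(fm, n_runs=2, n_trees=50, mtry=1, seed=0)
        table = rank_features(report)
        assert table.loc[0, "feature"] == "only"
        assert table.loc[0, "rank"] == 1

    def test_column_order_invariant(self):
        fm = planted_feature_matrix(seed=6, n_rows=120, n_noise=6)
        report1 = train_eval(fm, n_runs=3, n_trees=100, mtry=3, seed=3)
        reordered = FeatureMatrix(
            fm.data[list(fm.data.columns)[::-1]], fm.labels, fm.site_ids
        )
        report2 = train_eval(reordered, n_runs=3, n_trees=100, mtry=3, seed=3)
        t1 = rank_features(report1)
        t2 = rank_features(report2)
        assert list(t1["feature"].head(1)) == list(t2["feature"].head(1))
        assert t1.loc[0, "feature"] == "planted"
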