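import numpy as np
import pytest

import dhsdelta as dd
from dhsdelta.simulate import assay_panel, genes_from_frame, genes_to_frame


class TestGenome:
    def test_no_sites_still_produces_genes(self):
        cfg = dd.SimulationConfig(
            seed=1, n_chrom=1, chrom_length=2_000_000, n_genes=30, n_sites=0
        )
        genes, sites, _ = dd.simulate_genome(cfg)
        assert sites == [] and len(genes) == 30

    def test_deterministic_under_fixed_seed(self):
        cfg = dd.SimulationConfig(
            seed=5, n_chrom=1, chrom_length=2_000_000, n_genes=40, n_sites=200
        )
        g1, s1, _ = dd.simulate_genome(cfg)
        g2, s2, _ = dd.simulate_genome(cfg)
        assert s1 == s2
        assert [g.tss for g in g1] == [g.tss for g in g2]

    def test_sites_non_overlapping_and_in_bounds(self, small_dataset,
                                                 small_cfg):
        by_chrom = {}
        for s in small_dataset.sites:
            assert 0 <= s.start < s.end <= small_cfg.chrom_length
            by_chrom.setdefault(s.chrom, []).append(s)
        for sites in by_chrom.values():
            sites.sort(key=lambda s: s.start)
            for a, b in zip(sites, sites[1:]):
                assert a.end <= b.start

    def test_planted_promoter_fraction_recovered(self, small_dataset,
                                                 small_cfg):
        labels = dd.classify_promoter(small_dataset.sites, small_dataset.genes)
        frac = np.mean(labels == "promoter")
        n = small_cfg.n_sites
        tol = 3 * np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - small_cfg.frac_promoter) <= tol
        # the planted flag agrees exactly with the promoter classifier
        assert np.array_equal(labels == "promoter",
                              small_dataset.truth.promoter)

    def test_infeasible_packing_raises(self):
        cfg = dd.SimulationConfig(
            seed=1, n_chrom=1, chrom_length=2_000_000, n_genes=10,
            n_sites=1700,
        )
        with pytest.raises(Exception, match="chromosomes|genome too small"):
            dd.simulate_genome(cfg)


class TestCounts:
    def test_status_fractions_match_config(self, small_dataset, small_cfg):
        status = small_dataset.truth.status
        n = len(status)
        assert np.sum(status == "opened") == round(small_cfg.frac_open * n)
        assert np.sum(status == "closed") == round(small_cfg.frac_closed * n)

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = dd.SimulationConfig(
            seed=3, n_chrom=1, chrom_length=4_000_000, n_genes=50,
            n_sites=1000, dispersion=0.0, mean_log_mu=np.log(100.0),
            sd_log_mu=0.0, planted_lfc=0.0,
        )
        genes, sites, placement = dd.simulate_genome(cfg)
        m, _ = dd.simulate_counts(sites, cfg, placement)
        # undo the planted size factors via median-of-ratios, then check
        # var/mean ~ 1 across >=2000 normalized control draws
        norm = m.counts / dd.size_factors(m)
        ratio = norm.var(axis=1, ddof=1).mean() / norm.mean()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_planted_fold_change_recovered(self):
        cfg = dd.SimulationConfig(
            seed=4, n_chrom=1, chrom_length=6_000_000, n_genes=200,
            n_sites=2000, frac_open=0.10, planted_lfc=2.0,
        )
        genes, sites, placement = dd.simulate_genome(cfg)
        m, truth = dd.simulate_counts(sites, cfg, placement)
        norm = m.counts / dd.size_factors(m)
        cond = np.asarray(m.sample_condition)
        opened = truth.status == "opened"
        assert opened.sum() >= 100
        ratio = (
            norm[opened][:, cond == "treated"].mean()
            / norm[opened][:, cond == "control"].mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_null_lfc_keeps_labels_but_no_signal(self):
        cfg = dd.SimulationConfig(
            seed=5, n_chrom=1, chrom_length=4_000_000, n_genes=50,
            n_sites=500, planted_lfc=0.0,
        )
        genes, sites, placement = dd.simulate_genome(cfg)
        m, truth = dd.simulate_counts(sites, cfg, placement)
        assert set(truth.status) == {"opened", "closed", "stable"}
        res = dd.nb_test(m)
        assert (res["fdr"] < 0.05).sum() <= 3


class TestTracks:
    def test_poised_mark_enrichment_ratio(self, small_dataset, small_cfg):
        truth = small_dataset.truth
        track = small_dataset.tracks["poised_mark"]

        def mean_signal(mask):
            sites = [s for s, m in zip(small_dataset.sites, mask) if m]
            windows = [
                dd.GenomicInterval(s.chrom, s.center - 700, s.center + 700)
                for s in sites
            ]
            return track.interval_sums(windows).mean(), len(sites)

        ob, n_ob = mean_signal((truth.status == "opened") & truth.tf_bound)
        sb, n_sb = mean_signal((truth.status == "stable") & truth.tf_bound)
        assert min(n_ob, n_sb) >= 30
        assert ob / sb == pytest.approx(
            small_cfg.poised_mark_effect, rel=0.25
        )

    def test_neutral_assay_has_no_class_effect(self, small_dataset):
        truth = small_dataset.truth
        track = small_dataset.tracks["neutral_histone_1"]
        sums = track.interval_sums(
            [
                dd.GenomicInterval(s.chrom, s.center - 700, s.center + 700)
                for s in small_dataset.sites
            ]
        )
        ob = sums[(truth.status == "opened") & truth.tf_bound].mean()
        sb = sums[(truth.status == "stable") & truth.tf_bound].mean()
        assert ob / sb == pytest.approx(1.0, rel=0.25)

    def test_tf_peaks_cover_exactly_bound_sites(self, small_dataset):
        bound = small_dataset.truth.tf_bound
        mask = dd.intervals.overlapping_mask(
            small_dataset.sites, small_dataset.tf_peaks
        )
        assert np.array_equal(mask, bound)

    def test_deterministic_bedgraph_output(self, tmp_path):
        cfg = dd.SimulationConfig(
            seed=9, n_chrom=1, chrom_length=2_000_000, n_genes=40, n_sites=200
        )
        texts = []
        for rep in range(2):
            ds = dd.simulate_dataset(cfg)
            p = tmp_path / f"t{rep}.bedGraph"
            dd.write_bedgraph(ds.tracks["poised_mark"], p)
            texts.append(p.read_bytes())
        assert texts[0] == texts[1]


class TestExpression:
    def test_full_coupling_unit_effect(self):
        cfg = dd.SimulationConfig(
            seed=6, n_chrom=2, chrom_length=6_000_000, n_genes=250,
            n_sites=1500, expr_coupling=1.0,
        )
        genes, sites, placement = dd.simulate_genome(cfg)
        m, truth = dd.simulate_counts(sites, cfg, placement)
        expr = dd.simulate_expression(genes, sites, truth, cfg)
        site_map = dd.nearest_gene_map(sites, genes)
        per_gene_opened = {}
        for i, s in enumerate(sites):
            if truth.status[i] == "opened":
                g = site_map[s.name]
                per_gene_opened[g] = per_gene_opened.get(g, 0) + 1
        fc = expr.set_index("gene_id")["log2fc"]
        # genes with exactly k direction-matched sites average k * effect
        closed_genes = {
            site_map[s.name]
            for i, s in enumerate(sites)
            if truth.status[i] == "closed"
        }
        for k in (1, 2):
            members = [
                g for g, c in per_gene_opened.items()
                if c == k and g not in closed_genes
            ]
            if len(members) >= 5:
                assert fc.loc[members].mean() == pytest.approx(
                    k * cfg.expr_effect, abs=0.5
                )

    def test_zero_coupling_is_null(self):
        cfg = dd.SimulationConfig(
            seed=7, n_chrom=1, chrom_length=4_000_000, n_genes=150,
            n_sites=800, expr_coupling=0.0,
        )
        genes, sites, placement = dd.simulate_genome(cfg)
        m, truth = dd.simulate_counts(sites, cfg, placement)
        expr = dd.simulate_expression(genes, sites, truth, cfg)
        assert (expr["fdr"] < 0.05).sum() == 0
        assert abs(expr["log2fc"].mean()) < 0.15


class TestDatasetFiles:
    def test_emitted_files_reread_consistently(self, small_dataset, tmp_path):
        paths = dd.write_dataset(small_dataset, tmp_path)
        sites = dd.read_bed(paths["sites"])
        assert sites == small_dataset.sites
        track = dd.read_bedgraph(paths["track:dnase"])
        assert track.total_signal == pytest.approx(
            small_dataset.tracks["dnase"].total_signal
        )
        genes = genes_from_frame(
            __import__("pandas").read_csv(paths["genes"], sep="\t")
        )
        assert [g.gene_id for g in genes] == [
            g.gene_id for g in small_dataset.genes
        ]
        truth = __import__("pandas").read_csv(paths["truth"], sep="\t")
        assert sorted(truth["status"].unique()) == sorted(
            set(small_dataset.truth.status)
        )

    def test_assay_panel_has_one_neutral_negative_control_minimum(self):
        panel = assay_panel(dd.SimulationConfig())
        assert (panel["role"] == "neutral").sum() >= 1
        assert set(panel["feature_class"]) == {
            "tf", "histone_mod", "chromatin_modifier"
        }
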