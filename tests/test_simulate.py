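import numpy as np
import pytest
from scipy import stats

from sirnaclust.annotation import write_gff3
from sirnaclust.simulate import (
    GroundTruth,
    SimulationConfig,
    plant_clusters,
    simulate_annotation,
    simulate_conservation,
    simulate_dataset,
    simulate_expression,
    simulate_reads,
    write_dataset,
)


class TestConfigValidation:
    def test_positive_rho_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(anticorrelation_rho=0.3)

    def test_length_dist_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(read_length_dist=((21, 0.5), (24, 0.4)))

    def test_length_support_in_18_30(self):
        with pytest.raises(ValueError):
            SimulationConfig(read_length_dist=((17, 0.5), (24, 0.5)))

    def test_short_planted_span_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cluster_span_range=(50, 200))

    def test_unknown_mapping_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_mapping({"seed": 1, "bogus": 2})


class TestSimulateAnnotation:
    def test_zero_genes_gives_empty_set_valid_layout(self):
        genes, layout = simulate_annotation(SimulationConfig(n_genes=0))
        assert genes == []
        assert set(layout.chrom_sizes) == {"chr1", "chr2"}
        assert set(layout.centromeres) == {"chr1", "chr2"}

    def test_same_seed_gives_byte_identical_gff3(self, tmp_path):
        for name in ("a.gff3", "b.gff3"):
            genes, layout = simulate_annotation(SimulationConfig(seed=3))
            write_gff3(genes, tmp_path / name, layout=layout)
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_gene_bodies_pairwise_disjoint(self):
        genes, _ = simulate_annotation(SimulationConfig(seed=4, n_genes=50))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.body.chrom, []).append(g.body)
        for bodies in by_chrom.values():
            bodies.sort(key=lambda iv: iv.start)
            for a, b in zip(bodies, bodies[1:]):
                assert a.end <= b.start

    def test_every_gene_has_introns_cds_and_utrs(self):
        genes, _ = simulate_annotation(SimulationConfig(seed=5, n_genes=20))
        for g in genes:
            assert g.introns()
            assert g.feature_intervals("cds")
            assert g.feature_intervals("five_prime_utr")
            assert g.feature_intervals("three_prime_utr")

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_annotation(SimulationConfig(n_genes=50, chrom_length=50_000))


class TestPlantClusters:
    def test_planted_intervals_inside_declared_host_feature(self, default_dataset):
        ds = default_dataset
        by_id = {g.gene_id: g for g in ds.genes}
        for pc in ds.truth.clusters:
            gene = by_id[pc.gene_id]
            assert any(
                iv.contains(pc.interval) for iv in gene.feature_intervals(pc.feature)
            )

    def test_planted_clusters_meet_detectability_floor(self, default_dataset):
        for pc in default_dataset.truth.clusters:
            assert pc.interval.length() >= 100
            assert all(n >= 10 for n in pc.counts.values())

    def test_ground_truth_json_round_trip(self, tmp_path, small_dataset):
        p = tmp_path / "truth.json"
        small_dataset.truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.rho == small_dataset.truth.rho
        assert [c.interval for c in back.clusters] == [
            c.interval for c in small_dataset.truth.clusters
        ]
        assert [c.counts for c in back.clusters] == [
            c.counts for c in small_dataset.truth.clusters
        ]


class TestSimulateReads:
    def test_zero_background_keeps_all_reads_in_planted_spans(self):
        cfg = SimulationConfig(seed=9, background_rate=0.0, n_contaminant_reads=0)
        genes, layout = simulate_annotation(cfg)
        truth = plant_clusters(cfg, genes)
        libs = simulate_reads(cfg, layout, truth)
        spans = [(c.interval.chrom, c.interval.start, c.interval.end) for c in truth.clusters]
        for df in libs.values():
            for row in df.itertuples(index=False):
                assert any(
                    row.chrom == c and row.start >= s and row.start < e
                    for c, s, e in spans
                )

    def test_planted_counts_match_truth_exactly(self, small_dataset):
        ds = small_dataset
        for label, df in ds.libraries.items():
            for pc in ds.truth.clusters:
                n = (
                    (df["chrom"] == pc.interval.chrom)
                    & (df["start"] >= pc.interval.start)
                    & (df["start"] < pc.interval.end)
                    & (~df["read_id"].str.contains("cont"))
                ).sum()
                # background can land inside the span too, so at least the
                # planted count and at most a handful more
                assert pc.counts[label] <= n <= pc.counts[label] + 10

    def test_length_histogram_matches_multinomial_within_3_se(self):
        cfg = SimulationConfig(seed=10, background_rate=60.0, n_contaminant_reads=0,
                               out_of_range_fraction=0.0)
        genes, layout = simulate_annotation(cfg)
        truth = plant_clusters(cfg, genes)
        libs = simulate_reads(cfg, layout, truth)
        lengths = np.concatenate([df["length"].to_numpy() for df in libs.values()])
        n = len(lengths)
        assert n > 1e5
        for length, p in cfg.length_dist.items():
            freq = (lengths == length).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3.5 * se, (length, freq, p)
        counts = {l: (lengths == l).sum() for l in range(18, 31)}
        ranked = sorted(counts, key=counts.get, reverse=True)
        assert set(ranked[:2]) == {21, 24}


class TestSimulateExpression:
    def _sampled_r(self, rho, seed, n_pairs=500):
        cfg = SimulationConfig(
            seed=seed,
            anticorrelation_rho=rho,
            n_chroms=2,
            chrom_length=2_000_000,
            n_genes=520,
            n_planted_clusters=n_pairs,
            n_silent_genes=0,
        )
        genes, _ = simulate_annotation(cfg)
        truth = plant_clusters(cfg, genes)
        gene_fcs, cluster_fcs = [], []
        for pc in truth.clusters:
            for plant in cfg.plants:
                for t0, t1 in zip(cfg.time_points, cfg.time_points[1:]):
                    label = f"{t0}-{t1}"
                    gene_fcs.append(pc.gene_log2fc[plant][label])
                    c0 = pc.counts[f"{plant}_{t0}"]
                    c1 = pc.counts[f"{plant}_{t1}"]
                    cluster_fcs.append(np.log2(c1 / c0))
        r, _ = stats.pearsonr(gene_fcs, cluster_fcs)
        return r

    def test_zero_rho_gives_near_zero_sample_correlation(self):
        assert abs(self._sampled_r(0.0, seed=21)) < 0.1

    def test_strong_negative_rho_recovered(self):
        assert self._sampled_r(-0.8, seed=22) == pytest.approx(-0.8, abs=0.1)

    def test_silent_gene_removed_by_floor_filter(self, default_dataset):
        from sirnaclust.association import filter_expressed_genes

        ds = default_dataset
        silent = ds.expression.index[(ds.expression <= 1.0).all(axis=1)]
        assert len(silent) == ds.config.n_silent_genes
        kept = filter_expressed_genes(ds.expression, plant="WT")
        assert not set(silent) & set(kept.index)

    def test_host_gene_fpkm_follows_planted_fold_changes(self, small_dataset):
        ds = small_dataset
        pc = ds.truth.clusters[0]
        f0 = ds.expression.at[pc.gene_id, "WT_0"]
        f1 = ds.expression.at[pc.gene_id, "WT_1"]
        assert np.log2(f1 / f0) == pytest.approx(pc.gene_log2fc["WT"]["0-1"], abs=1e-9)


class TestSimulateConservation:
    def test_scores_clipped_to_unit_interval(self, default_dataset):
        for arr in default_dataset.track.arrays.values():
            present = arr[~np.isnan(arr)]
            assert present.min() >= 0.0 and present.max() <= 1.0

    def test_intronic_uplift_close_to_configured_effect(self):
        cfg = SimulationConfig(seed=30, conservation_effect=0.3, conservation_noise_sd=0.1)
        genes, _ = simulate_annotation(cfg)
        truth = plant_clusters(cfg, genes)
        track = simulate_conservation(cfg, genes, truth)
        inside, outside = [], []
        uplift = {(iv.chrom, iv.start, iv.end) for iv in truth.uplift_intervals()}
        for gene in genes:
            for iv in gene.introns():
                arr = track.arrays[iv.chrom][iv.start:iv.end]
                covered = any(
                    c == iv.chrom and s < iv.end and iv.start < e for c, s, e in uplift
                )
                if not covered:
                    outside.append(arr)
        for c, s, e in uplift:
            inside.append(track.arrays[c][s:e])
        delta = np.concatenate(inside).mean() - np.concatenate(outside).mean()
        assert delta == pytest.approx(0.3, abs=0.03)

    def test_null_effect_leaves_clusters_indistinguishable(self):
        cfg = SimulationConfig(seed=31, conservation_effect=0.0)
        genes, _ = simulate_annotation(cfg)
        truth = plant_clusters(cfg, genes)
        track = simulate_conservation(cfg, genes, truth)
        inside = np.concatenate(
            [track.arrays[iv.chrom][iv.start:iv.end] for iv in truth.uplift_intervals()]
        )
        intron_all = np.concatenate(
            [track.arrays[iv.chrom][iv.start:iv.end] for g in genes for iv in g.introns()]
        )
        _, p = stats.ttest_ind(inside, intron_all[~np.isnan(intron_all)], equal_var=False)
        assert p > 0.01

    def test_bedgraph_round_trip(self, tmp_path, small_dataset):
        ds = small_dataset
        p = tmp_path / "cons.bedGraph"
        ds.track.to_bedgraph(p)
        from sirnaclust.conservation import ConservationTrack

        back = ConservationTrack.from_bedgraph(p, ds.layout.chrom_sizes)
        for chrom, arr in ds.track.arrays.items():
            b = back.arrays[chrom][: len(arr)]
            mask = ~np.isnan(arr)
            np.testing.assert_allclose(b[mask], np.round(arr[mask], 4), atol=1e-9)
            assert np.all(np.isnan(b[~mask]))


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(
            seed=12, n_chroms=1, chrom_length=300_000, n_genes=8,
            n_planted_clusters=4, background_rate=1.0, n_contaminant_reads=10,
        )
        for d in ("one", "two"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "one").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes(), name
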