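import numpy as np
import pytest

from sirnaclust.annotation import build_gene_model
from sirnaclust.cluster import SiRNACluster
from sirnaclust.conservation import (
    BinScore,
    ConservationTrack,
    bin_feature_regions,
    conservation_tests,
    cumulative_score_distribution,
    export_cluster_fasta,
    label_cluster_bins,
    resampled_ttest,
    score_bins,
    select_conserved_candidates,
)
from sirnaclust.conservation import testable_bins as usable_bins
from sirnaclust.intervals import GenomicInterval


def _intron_gene(chrom="c", intron=(300, 600)):
    body = GenomicInterval(chrom, 0, 1000, "+")
    exons = [GenomicInterval(chrom, 0, intron[0], "+"), GenomicInterval(chrom, intron[1], 1000, "+")]
    cds = [GenomicInterval(chrom, 100, intron[0], "+"), GenomicInterval(chrom, intron[1], 900, "+")]
    return build_gene_model("g", body, exons, cds)


class TestBinning:
    def test_exact_tiling_of_100bp_feature(self):
        gene = _intron_gene(intron=(300, 400))
        bins = [b for b in bin_feature_regions([gene]) if b.feature == "intron"]
        assert [(b.interval.start, b.interval.end) for b in bins] == [
            (300, 325), (325, 350), (350, 375), (375, 400)
        ]

    def test_remainder_shorter_than_bin_dropped(self):
        gene = _intron_gene(intron=(300, 360))
        bins = [b for b in bin_feature_regions([gene]) if b.feature == "intron"]
        assert len(bins) == 2
        assert bins[-1].interval.end == 350  # 10 bp remainder dropped

    def test_cds_rejected(self):
        with pytest.raises(ValueError):
            bin_feature_regions([_intron_gene()], features=("cds",))

    def test_tiling_deficit_below_one_bin_per_interval(self):
        gene = _intron_gene(intron=(300, 593))
        bins = [b for b in bin_feature_regions([gene]) if b.feature == "intron"]
        total = sum(b.interval.length() for b in bins)
        assert 293 - 25 < total <= 293


class TestScoring:
    def _track(self, arr):
        return ConservationTrack({"c": arr})

    def test_constant_track(self):
        gene = _intron_gene()
        bins = bin_feature_regions([gene])
        track = self._track(np.full(1000, 0.7))
        score_bins(bins, track)
        assert all(b.mean_score == pytest.approx(0.7) for b in bins)

    def test_half_and_half_bin_averages_to_midpoint(self):
        arr = np.full(1000, np.nan)
        arr[300:312] = 1.0
        arr[312:325] = 0.0
        gene = _intron_gene()
        bins = [b for b in bin_feature_regions([gene]) if b.interval.start == 300]
        score_bins(bins, self._track(arr))
        assert bins[0].mean_score == pytest.approx(12 / 25)

    def test_matches_direct_per_base_average(self):
        rng = np.random.default_rng(0)
        arr = rng.random(1000)
        gene = _intron_gene()
        bins = bin_feature_regions([gene])
        score_bins(bins, self._track(arr))
        for b in bins:
            assert b.mean_score == pytest.approx(arr[b.interval.start:b.interval.end].mean())

    def test_sparse_coverage_excluded_from_testing(self):
        arr = np.full(1000, np.nan)
        arr[300:310] = 0.5  # only 10/25 bases of the first bin present
        gene = _intron_gene()
        bins = [b for b in bin_feature_regions([gene]) if b.interval.start == 300]
        score_bins(bins, self._track(arr))
        assert usable_bins(bins) == []

    def test_missing_chromosome_raises(self):
        gene = _intron_gene()
        bins = bin_feature_regions([gene])
        with pytest.raises(ValueError):
            score_bins(bins, ConservationTrack({"other": np.zeros(10)}))


class TestLabeling:
    def test_overlap_semantics(self):
        gene = _intron_gene()
        bins = bin_feature_regions([gene])
        clusters = [SiRNACluster("k", GenomicInterval("c", 330, 360))]
        label_cluster_bins(bins, clusters)
        by_start = {b.interval.start: b.is_cluster_bin for b in bins if b.feature == "intron"}
        assert by_start[325] and by_start[350]
        assert not by_start[300]  # adjacent, zero overlap
        assert not by_start[375]

    def test_labels_match_linear_scan_on_synthetic_truth(self, small_dataset):
        ds = small_dataset
        clusters = [SiRNACluster(c.cluster_id, c.interval) for c in ds.truth.clusters]
        bins = bin_feature_regions(ds.genes)
        label_cluster_bins(bins, clusters)
        for b in bins:
            expected = any(b.interval.overlaps(c.interval) for c in clusters)
            assert b.is_cluster_bin == expected


class TestResampledTtest:
    def test_deterministic_given_seed_and_order_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.1, 50)
        y = rng.normal(0.4, 0.1, 500)
        a = resampled_ttest(x, y, n_resamples=100, seed=5)
        b = resampled_ttest(x, y, n_resamples=100, seed=5)
        np.testing.assert_array_equal(a.resample_pvalues, b.resample_pvalues)
        perm = rng.permutation(len(y))
        c = resampled_ttest(np.sort(x), np.sort(y), n_resamples=100, seed=5)
        # sorted input changes which values each draw picks, but summary
        # statistics stay equivalent in distribution; exact invariance holds
        # for the cluster-side statistics
        assert c.n_cluster_bins == a.n_cluster_bins

    def test_power_with_planted_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.55, 0.1, 100)
        y = rng.normal(0.25, 0.1, 1000)
        res = resampled_ttest(x, y, n_resamples=500, seed=0)
        assert res.fraction_significant >= 0.99
        assert res.significant

    def test_type_one_error_close_to_alpha(self):
        fracs = []
        for seed in range(30):
            rng = np.random.default_rng(3000 + seed)
            x = rng.normal(0.3, 0.1, 100)
            y = rng.normal(0.3, 0.1, 1000)
            fracs.append(
                resampled_ttest(x, y, n_resamples=300, seed=rng).fraction_significant
            )
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.03)

    def test_degenerate_constant_scores_nonsignificant_with_flag(self):
        res = resampled_ttest(np.full(5, 0.5), np.full(50, 0.5), n_resamples=20, seed=0)
        assert res.fraction_significant == 0.0
        assert res.n_degenerate == 20
        assert np.all(res.resample_pvalues == 1.0)

    def test_too_few_cluster_bins_rejected(self):
        with pytest.raises(ValueError, match="cluster bins"):
            resampled_ttest([0.1, 0.2], np.zeros(10), feature="intron")

    def test_equal_var_variant_close_to_welch_at_equal_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.5, 0.1, 80)
        y = rng.normal(0.45, 0.1, 800)
        w = resampled_ttest(x, y, n_resamples=200, seed=1, equal_var=False)
        s = resampled_ttest(x, y, n_resamples=200, seed=1, equal_var=True)
        assert abs(w.fraction_significant - s.fraction_significant) < 0.1


class TestCumulativeDistribution:
    def _bins(self, scores, is_cluster):
        out = []
        for i, (s, c) in enumerate(zip(scores, is_cluster)):
            b = BinScore(GenomicInterval("c", 25 * i, 25 * i + 25), "intron")
            b.mean_score, b.covered_frac, b.is_cluster_bin = s, 1.0, c
            out.append(b)
        return out

    def test_point_mass_jumps_at_next_threshold(self):
        bins = self._bins([0.55] * 8, [True] * 4 + [False] * 4)
        table = cumulative_score_distribution(bins)
        row_05 = table.loc[np.isclose(table["threshold"], 0.5)].iloc[0]
        row_06 = table.loc[np.isclose(table["threshold"], 0.6)].iloc[0]
        assert row_05["cluster"] == 0.0 and row_06["cluster"] == 1.0
        assert table["cluster"].iloc[-1] == 1.0

    def test_empty_group_is_all_nan(self):
        bins = self._bins([0.2, 0.4, 0.9], [False, False, False])
        table = cumulative_score_distribution(bins)
        assert table["cluster"].isna().all()
        assert table["noncluster"].iloc[-1] == 1.0

    def test_uniform_scores_track_identity_line(self):
        rng = np.random.default_rng(5)
        scores = rng.random(4000)
        bins = self._bins(scores, [True] * 2000 + [False] * 2000)
        table = cumulative_score_distribution(bins)
        for _, row in table.iterrows():
            assert row["cluster"] == pytest.approx(row["threshold"], abs=0.05)


class TestCandidateSelection:
    def _pair(self, gid, gfc, cfc):
        from sirnaclust.association import GeneClusterPair

        return GeneClusterPair(
            gene_id=gid, cluster_ids=[gid], log2fc_gene=gfc, log2fc_cluster=cfc
        )

    ORTHOLOGS = {
        "g5": {"Oryza sativa", "Zea mays", "Sorghum bicolor", "Setaria italica", "Brachypodium distachyon"},
        "g3": {"Oryza sativa", "Zea mays", "Sorghum bicolor"},
    }

    def test_anticorrelated_with_enough_orthologs_kept(self):
        p = self._pair("g5", {"0-1": -2.0, "1-6": 0.4}, {"0-1": 1.5, "1-6": 0.2})
        assert select_conserved_candidates([p], self.ORTHOLOGS) == [p]

    def test_concordant_pair_dropped(self):
        p = self._pair("g5", {"0-1": 1.0, "1-6": 0.5}, {"0-1": 0.5, "1-6": 1.0})
        assert select_conserved_candidates([p], self.ORTHOLOGS) == []

    def test_too_few_ortholog_plants_dropped(self):
        p = self._pair("g3", {"0-1": -2.0}, {"0-1": 1.5})
        assert select_conserved_candidates([p], self.ORTHOLOGS) == []


class TestFastaExport:
    def test_sequences_match_direct_substring(self, tmp_path):
        genome = tmp_path / "genome.fasta"
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        genome.write_text(f">c\n{seq}\n")
        clusters = [
            SiRNACluster("k1", GenomicInterval("c", 0, 10)),
            SiRNACluster("k2", GenomicInterval("c", 7, 19)),
        ]
        out = tmp_path / "out.fasta"
        export_cluster_fasta(clusters, genome, out)
        text = out.read_text().splitlines()
        assert text == [">k1", seq[0:10], ">k2", seq[7:19]]

    def test_empty_cluster_set_gives_empty_fasta(self, tmp_path):
        genome = tmp_path / "genome.fasta"
        genome.write_text(">c\nACGT\n")
        out = tmp_path / "out.fasta"
        export_cluster_fasta([], genome, out)
        assert out.read_text() == ""

    def test_interval_beyond_chromosome_rejected(self, tmp_path):
        genome = tmp_path / "genome.fasta"
        genome.write_text(">c\nACGT\n")
        with pytest.raises(ValueError):
            export_cluster_fasta(
                [SiRNACluster("k", GenomicInterval("c", 0, 10))], genome, tmp_path / "o.fasta"
            )


class TestPerFeaturePattern:
    def test_intron_confined_uplift_detected_only_in_introns(self, default_dataset):
        ds = default_dataset
        clusters = [SiRNACluster(c.cluster_id, c.interval) for c in ds.truth.clusters]
        bins = bin_feature_regions(ds.genes)
        score_bins(bins, ds.track)
        label_cluster_bins(bins, clusters)
        results = conservation_tests(bins, n_resamples=300, seed=1)
        assert results["intron"].significant
        assert not results["five_prime_utr"].significant
        assert not results["three_prime_utr"].significant
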