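import numpy as np
import pytest

from sirnaclust.cluster import (
    ClusterParams,
    KDistProfile,
    SiRNACluster,
    dbscan_1d,
    dbscan_labels,
    detect_plant_clusters,
    detect_sample_clusters,
    kdist,
    merge_clusters,
    select_epsilon,
)
from sirnaclust.evaluate import score_detection
from sirnaclust.intervals import GenomicInterval
from sirnaclust.preprocess import preprocess_library

from conftest import dbscan_bruteforce, kdist_bruteforce, merge_bruteforce


class TestKDist:
    def test_equally_spaced_points(self):
        prof = kdist(np.array([0, 100, 200, 300]), k=1)
        assert list(prof.values) == [100, 100, 100, 100]

    def test_identical_positions_all_zero(self):
        prof = kdist(np.full(11, 42), k=10)
        assert np.all(prof.values == 0)

    def test_too_few_positions_warns_and_empty(self):
        with pytest.warns(UserWarning):
            prof = kdist(np.arange(5), k=10)
        assert len(prof) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 20_000, size=400)
        got = kdist(pos, 30).values
        expected = kdist_bruteforce(pos, 30)
        np.testing.assert_allclose(got, expected)

    def test_profile_rejects_increasing_values(self):
        with pytest.raises(ValueError):
            KDistProfile(k=1, values=np.array([1.0, 2.0]))


def _chord_knee_oracle(values):
    """Exhaustive max-perpendicular-distance search on normalized axes."""
    v = np.asarray(values, float)
    n = len(v)
    x = np.arange(n) / (n - 1)
    y = (v - v[-1]) / (v[0] - v[-1])
    best_i, best_d = 0, -1.0
    for i in range(n):
        d = abs(x[i] + y[i] - 1.0) / np.sqrt(2)
        if d > best_d + 1e-12:
            best_i, best_d = i, d
    return best_i


class TestSelectEpsilon:
    def test_piecewise_profile_breaks_at_floor(self):
        # plateau at 1000, linear descent, long flat tail at 100
        values = np.concatenate(
            [np.full(50, 1000.0), np.linspace(1000, 100, 11)[1:], np.full(140, 100.0)]
        )
        sel = select_epsilon(KDistProfile(k=30, values=values))
        assert sel.epsilon == 100.0
        assert sel.index == _chord_knee_oracle(values)
        assert not sel.low_confidence

    def test_strictly_linear_profile_flagged_low_confidence(self):
        # every point lies on the chord: no valley exists, only float noise
        values = np.linspace(500, 100, 50)
        sel = select_epsilon(KDistProfile(k=30, values=values))
        assert sel.low_confidence

    def test_uniform_profile_raises(self):
        with pytest.raises(ValueError, match="uniform"):
            select_epsilon(KDistProfile(k=30, values=np.full(30, 7.0)))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_random_descending(self, seed):
        rng = np.random.default_rng(seed)
        values = np.sort(rng.exponential(200, size=200))[::-1]
        sel = select_epsilon(KDistProfile(k=30, values=values))
        assert sel.index == _chord_knee_oracle(values)
        assert sel.epsilon == values[sel.index]


class TestDbscan1d:
    def test_dense_run_forms_single_cluster(self):
        starts = np.arange(0, 100, 10)  # 10 reads, pairwise <= 90 apart
        ends = starts + 24
        out = dbscan_1d(starts, ends, ClusterParams(epsilon=100, minpts=10), chrom="c")
        assert len(out) == 1
        hull, members = out[0]
        assert (hull.start, hull.end) == (0, 114)
        assert len(members) == 10

    def test_nine_identical_reads_below_minpts(self):
        starts = np.full(9, 500)
        out = dbscan_1d(starts, starts + 24, ClusterParams(epsilon=100, minpts=10))
        assert out == []

    @pytest.mark.parametrize("seed", range(10))
    def test_labels_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(50, 400))
        starts = rng.integers(0, 5000, size=n)
        eps = float(rng.integers(20, 200))
        minpts = int(rng.integers(3, 12))
        got = dbscan_labels(starts, eps, minpts)
        expected = dbscan_bruteforce(starts, eps, minpts)
        np.testing.assert_array_equal(got, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 3000, size=200)
        labels = dbscan_labels(starts, 80, 5)
        perm = rng.permutation(len(starts))
        labels_perm = dbscan_labels(starts[perm], 80, 5)
        np.testing.assert_array_equal(labels[perm], labels_perm)

    def test_members_within_hull_and_noise_accounted(self):
        rng = np.random.default_rng(9)
        starts = np.concatenate([rng.integers(0, 200, 40), rng.integers(4000, 4100, 30)])
        ends = starts + 24
        out = dbscan_1d(starts, ends, ClusterParams(epsilon=50, minpts=10), chrom="c")
        clustered = np.concatenate([m for _, m in out]) if out else np.array([], int)
        assert len(set(clustered)) == len(clustered)  # no point in two clusters
        for hull, members in out:
            assert starts[members].min() >= hull.start
            assert ends[members].max() <= hull.end


class TestDetectAndMerge:
    def test_empty_library_gives_no_clusters(self):
        from sirnaclust.preprocess import reads_to_frame

        lib = preprocess_library(reads_to_frame([]), "WT", 0)
        assert detect_sample_clusters(lib, ClusterParams()) == []

    def test_detected_clusters_hold_at_least_minpts_weighted_reads(self, default_dataset):
        ds = default_dataset
        lib = preprocess_library(ds.libraries["WT_0"], "WT", 0, filter_seqs=ds.filter_seqs)
        found = detect_sample_clusters(lib, ClusterParams(epsilon=100, minpts=10))
        assert found
        for c in found:
            assert c.n_reads["WT_0"] >= 10

    def test_halved_epsilon_clusters_nest_in_default_clusters(self, default_dataset):
        ds = default_dataset
        lib = preprocess_library(ds.libraries["WT_0"], "WT", 0, filter_seqs=ds.filter_seqs)
        wide = detect_sample_clusters(lib, ClusterParams(epsilon=100, minpts=10))
        narrow = detect_sample_clusters(lib, ClusterParams(epsilon=50, minpts=10))
        for c in narrow:
            assert any(w.interval.contains(c.interval) for w in wide)

    def test_merge_examples(self):
        a = SiRNACluster("a", GenomicInterval("c", 0, 100), {"WT_0": 12.0}, {"WT_0": 5.0})
        b = SiRNACluster("b", GenomicInterval("c", 50, 150), {"WT_6": 20.0}, {"WT_6": 8.0})
        (m,) = merge_clusters([a], [b])
        assert (m.interval.start, m.interval.end) == (0, 150)
        assert m.n_reads == {"WT_0": 12.0, "WT_6": 20.0}
        assert m.rpm == {"WT_0": 5.0, "WT_6": 8.0}

        c = SiRNACluster("c", GenomicInterval("c", 200, 300), {"WT_0": 11.0}, {})
        merged = merge_clusters([a, c])
        assert [(m.interval.start, m.interval.end) for m in merged] == [(0, 100), (200, 300)]

    def test_merge_matches_sweep_line_oracle(self):
        rng = np.random.default_rng(3)
        clusters = []
        for i in range(200):
            s = int(rng.integers(0, 20_000))
            clusters.append(
                SiRNACluster(
                    f"c{i}",
                    GenomicInterval("c", s, s + int(rng.integers(50, 400))),
                    {"WT_0": 1.0},
                    {"WT_0": 1.0},
                )
            )
        merged = merge_clusters(clusters)
        expected = merge_bruteforce([c.interval for c in clusters])
        assert [(m.interval.chrom, m.interval.start, m.interval.end) for m in merged] == expected
        # counts conserved under merging
        assert sum(m.n_reads["WT_0"] for m in merged) == pytest.approx(200.0)
        for a, b in zip(merged, merged[1:]):
            assert a.interval.end <= b.interval.start

    def test_planted_cluster_recovery(self, default_dataset):
        ds = default_dataset
        libs = [
            preprocess_library(ds.libraries[f"WT_{t}"], "WT", t, filter_seqs=ds.filter_seqs)
            for t in (0, 1, 6)
        ]
        merged = detect_plant_clusters(libs, ClusterParams(epsilon=100, minpts=10))
        score = score_detection(merged, ds.truth)
        assert score.recall >= 0.95
        assert score.precision >= 0.95
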