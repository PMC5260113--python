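"""Evolutionary conservation analysis of cluster regions.

Per-base conservation probabilities (a phastCons-style track in [0, 1],
consumed as bedGraph in reference coordinates) are averaged over
consecutive 25-nt bins tiled across 5'UTR, 3'UTR and intron intervals; CDS
regions are excluded up front because their uniformly high scores swamp
the comparison. Bins overlapping a merged siRNA cluster by >= 1 bp are
cluster bins, the rest non-cluster bins. Because cluster bins are the
rarer class, the two-sample comparison is repeated over many (default
1000) size-matched random draws of non-cluster bins; each draw is tested
with Welch's two-sided t-test and the result is summarized by the median
p-value and the fraction of draws with p <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .annotation import GeneModel
from .cluster import SiRNACluster
from .intervals import GenomicInterval, IntervalIndex

TESTABLE_FEATURES = ("five_prime_utr", "three_prime_utr", "intron")
BIN_SIZE = 25


class ConservationTrack:
    """Per-base conservation scores per chromosome; NaN marks missing bases."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays
        for chrom, arr in arrays.items():
            present = arr[~np.isnan(arr)]
            if len(present) and (present.min() < 0 or present.max() > 1):
                raise ValueError(f"scores outside [0, 1] on {chrom}")

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom_sizes: dict[str, int]) -> "ConservationTrack":
        arrays = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "score"], dtype={"chrom": str},
        )
        for row in df.itertuples(index=False):
            if row.chrom not in arrays:
                raise ValueError(f"bedGraph chromosome {row.chrom!r} not in genome")
            arrays[row.chrom][int(row.start):int(row.end)] = float(row.score)
        return cls(arrays)

    def to_bedgraph(self, path: str | Path, decimals: int = 4) -> None:
        """Run-length-encoded bedGraph; missing (NaN) bases are skipped."""
        with open(path, "w") as fh:
            for chrom in sorted(self.arrays):
                arr = np.round(self.arrays[chrom], decimals)
                n = len(arr)
                if n == 0:
                    continue
                # break runs where the value changes or data is missing
                isnan = np.isnan(arr)
                change = np.flatnonzero(
                    (arr[1:] != arr[:-1]) & ~(isnan[1:] & isnan[:-1])
                ) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [n]])
                for s, e in zip(starts, ends):
                    if not isnan[s]:
                        fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.{decimals}f}\n")

    def mean_over(self, interval: GenomicInterval) -> tuple[float, float]:
        """(mean over present bases, covered fraction) for an interval."""
        arr = self.arrays.get(interval.chrom)
        if arr is None:
            raise ValueError(f"chromosome {interval.chrom!r} absent from track")
        window = arr[interval.start:interval.end]
        present = ~np.isnan(window)
        frac = present.mean() if len(window) else 0.0
        mean = float(window[present].mean()) if present.any() else float("nan")
        return mean, float(frac)


@dataclass
class BinScore:
    """One 25-nt bin of a gene sub-feature."""

    interval: GenomicInterval
    feature: str
    gene_id: str | None = None
    mean_score: float = float("nan")
    covered_frac: float = 0.0
    is_cluster_bin: bool | None = None


def bin_feature_regions(
    genes: list[GeneModel],
    bin_size: int = BIN_SIZE,
    features: tuple[str, ...] = TESTABLE_FEATURES,
) -> list[BinScore]:
    """Tile UTR/intron intervals with consecutive ``bin_size``-nt bins.

    Bins are anchored at each feature interval's left edge; a remainder
    shorter than ``bin_size`` is dropped. CDS regions are rejected.
    """
    for f in features:
        if f not in TESTABLE_FEATURES:
            raise ValueError(
                f"feature {f!r} is not binned for conservation testing (CDS excluded)"
            )
    bins: list[BinScore] = []
    for gene in genes:
        for label in features:
            for iv in gene.feature_intervals(label):
                for s in range(iv.start, iv.end - bin_size + 1, bin_size):
                    bins.append(
                        BinScore(
                            interval=GenomicInterval(iv.chrom, s, s + bin_size),
                            feature=label,
                            gene_id=gene.gene_id,
                        )
                    )
    return bins


def score_bins(
    bins: list[BinScore], track: ConservationTrack, min_coverage: float = 0.5
) -> list[BinScore]:
    """Assign each bin the mean track score over its present bases.

    Bins with < ``min_coverage`` of bases present keep mean NaN and are
    excluded from testing by :func:`testable_bins`.
    """
    for b in bins:
        mean, frac = track.mean_over(b.interval)
        b.covered_frac = frac
        b.mean_score = mean if frac >= min_coverage else float("nan")
    return bins


def testable_bins(bins: list[BinScore]) -> list[BinScore]:
    return [b for b in bins if not np.isnan(b.mean_score)]


def label_cluster_bins(bins: list[BinScore], clusters: list[SiRNACluster]) -> list[BinScore]:
    """Flag bins overlapping any merged cluster by >= 1 bp."""
    index = IntervalIndex(c.interval for c in clusters)
    for b in bins:
        b.is_cluster_bin = bool(index.overlapping(b.interval))
    return bins


@dataclass
class ConservationTestResult:
    """Outcome of the size-matched resampled two-sample test for one feature."""

    feature: str
    n_cluster_bins: int
    n_noncluster_bins: int
    resample_pvalues: np.ndarray
    alpha: float = 0.05
    n_degenerate: int = 0  # resamples with undefined t (zero variance), counted non-significant
    significance_threshold: float = 0.95

    @property
    def median_p(self) -> float:
        return float(np.median(self.resample_pvalues))

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.resample_pvalues <= self.alpha))

    @property
    def significant(self) -> bool:
        return self.fraction_significant >= self.significance_threshold


def resampled_ttest(
    cluster_scores,
    noncluster_scores,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    equal_var: bool = False,
    feature: str = "",
    significance_threshold: float = 0.95,
) -> ConservationTestResult:
    """Size-matched resampled t-test of cluster vs non-cluster bin scores.

    Each resample draws ``len(cluster_scores)`` non-cluster scores without
    replacement and runs a two-sided t-test (Welch by default; pooled
    variance with ``equal_var=True``) against the cluster scores.
    Deterministic given the seed. Resamples with zero variance in both
    groups and equal means have no defined t statistic and are reported as
    non-significant (p = 1) and counted in ``n_degenerate``.
    """
    x = np.asarray(cluster_scores, float)
    y = np.asarray(noncluster_scores, float)
    m, n = len(x), len(y)
    if m < 3:
        raise ValueError(f"need >= 3 cluster bins for feature {feature!r} (got {m})")
    if n < m:
        raise ValueError(
            f"need at least as many non-cluster bins as cluster bins for {feature!r}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.empty((n_resamples, m), dtype=np.int64)
    for i in range(n_resamples):
        idx[i] = rng.choice(n, size=m, replace=False)
    Y = y[idx]  # (n_resamples, m)

    mean_x, var_x = x.mean(), x.var(ddof=1)
    mean_y = Y.mean(axis=1)
    var_y = Y.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((m - 1) * var_x + (m - 1) * var_y) / (2 * m - 2)
        denom = np.sqrt(sp2 * (2.0 / m))
        dof = np.full(n_resamples, 2 * m - 2, dtype=float)
    else:
        vx, vy = var_x / m, var_y / m
        denom = np.sqrt(vx + vy)
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = (vx + vy) ** 2 / (vx**2 / (m - 1) + vy**2 / (m - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_x - mean_y) / denom
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = ~np.isfinite(t)
    p = np.where(degenerate, 1.0, p)
    return ConservationTestResult(
        feature=feature,
        n_cluster_bins=m,
        n_noncluster_bins=n,
        resample_pvalues=p,
        alpha=alpha,
        n_degenerate=int(degenerate.sum()),
        significance_threshold=significance_threshold,
    )


def conservation_tests(
    bins: list[BinScore],
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    equal_var: bool = False,
    significance_threshold: float = 0.95,
) -> dict[str, ConservationTestResult]:
    """Run the resampled test per feature on scored, labeled bins."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = {}
    for feature in TESTABLE_FEATURES:
        fb = [b for b in testable_bins(bins) if b.feature == feature]
        cl = [b.mean_score for b in fb if b.is_cluster_bin]
        ncl = [b.mean_score for b in fb if not b.is_cluster_bin]
        if len(cl) < 3 or len(ncl) < len(cl):
            continue
        results[feature] = resampled_ttest(
            cl,
            ncl,
            n_resamples=n_resamples,
            alpha=alpha,
            seed=rng,
            equal_var=equal_var,
            feature=feature,
            significance_threshold=significance_threshold,
        )
    return results


def cumulative_score_distribution(
    bins: list[BinScore], step: float = 0.1
) -> pd.DataFrame:
    """Cumulative fraction of bins at or below each score threshold.

    Thresholds run 0.0, 0.1, ..., 1.0; cluster and non-cluster bins are
    reported separately (NaN columns for empty groups). The final value of
    a non-empty group is 1.
    """
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    groups = {
        "cluster": np.array([b.mean_score for b in testable_bins(bins) if b.is_cluster_bin]),
        "noncluster": np.array(
            [b.mean_score for b in testable_bins(bins) if not b.is_cluster_bin]
        ),
    }
    data = {"threshold": thresholds}
    for name, scores in groups.items():
        if len(scores) == 0:
            data[name] = np.full(len(thresholds), np.nan)
        else:
            data[name] = np.array([(scores <= t).mean() for t in thresholds])
    return pd.DataFrame(data)


def select_conserved_candidates(
    pairs,
    orthologs: dict[str, set[str]],
    min_plants: int = 4,
    reference: str = "Oryza sativa",
) -> list:
    """Keep gene/cluster pairs that look regulatory and alignable.

    A pair qualifies when gene and cluster log2 fold changes have opposite
    (strict) signs in at least one time interval, and the gene has
    orthologs in >= ``min_plants`` species including the reference.
    """
    kept = []
    for pair in pairs:
        anti = any(
            pair.log2fc_gene[i] * pair.log2fc_cluster[i] < 0 for i in pair.log2fc_gene
        )
        plants = orthologs.get(pair.gene_id, set())
        if anti and reference in plants and len(plants) >= min_plants:
            kept.append(pair)
    return kept


def read_ortholog_table(path: str | Path) -> dict[str, set[str]]:
    """TSV (gene_id, plant, ortholog_id) -> gene_id -> set of plants."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "plant", "ortholog_id"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), set()).add(str(row.plant))
    return out


def export_cluster_fasta(
    clusters: list[SiRNACluster], genome_fasta: str | Path, out_path: str | Path
) -> None:
    """Write plus-strand genomic sequences of clusters (e.g. motif-search input)."""
    genome = Fasta(str(genome_fasta))
    with open(out_path, "w") as fh:
        for c in clusters:
            chrom = c.interval.chrom
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} absent from genome FASTA")
            if c.interval.end > len(genome[chrom]):
                raise ValueError(
                    f"cluster {c.cluster_id} exceeds chromosome {chrom} length"
                )
            seq = genome[chrom][c.interval.start:c.interval.end].seq
            fh.write(f">{c.cluster_id}\n{seq}\n")


def write_test_results_tsv(results: dict[str, ConservationTestResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature\tn_cluster_bins\tn_noncluster_bins\tmedian_p\tfraction_significant\tsignificant\n"
        )
        for feature in sorted(results):
            r = results[feature]
            fh.write(
                f"{feature}\t{r.n_cluster_bins}\t{r.n_noncluster_bins}\t"
                f"{r.median_p:.6g}\t{r.fraction_significant:.4f}\t{r.significant}\n"
            )
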