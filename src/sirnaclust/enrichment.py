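"""Feature-wise cluster enrichment and chromosomal positioning.

Clusters are classified by the gene sub-feature they overlap most (introns
dominate in the drought data), and per-feature enrichment is reported as a
length-normalized odds ratio: the density of clusters in a feature class
relative to the density in all other classes, so that the much shorter
UTRs are not penalized for harboring fewer clusters in absolute terms.
Chromosome-scale positioning is profiled as the relative arm position of
each cluster between the centromere edge (0) and the chromosome end (1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel
from .cluster import SiRNACluster
from .intervals import GenomeLayout

#: classification tie-break priority, highest first
FEATURE_PRIORITY = ("intron", "cds", "five_prime_utr", "three_prime_utr")


def classify_cluster_feature(cluster: SiRNACluster, gene: GeneModel) -> str:
    """Feature label with maximal bp overlap with the cluster interval.

    Ties go to the higher-priority label (intron > cds > 5'UTR > 3'UTR);
    a cluster overlapping none of the annotated sub-features is
    "other_genic".
    """
    overlaps = {}
    for label in FEATURE_PRIORITY:
        bp = sum(cluster.interval.overlap_length(iv) for iv in gene.feature_intervals(label))
        if bp > 0:
            overlaps[label] = bp
    if not overlaps:
        return "other_genic"
    best_bp = max(overlaps.values())
    for label in FEATURE_PRIORITY:
        if overlaps.get(label) == best_bp:
            return label
    raise AssertionError("unreachable")


@dataclass
class FeatureEnrichment:
    """Length-normalized cluster enrichment per feature class."""

    n_clusters: dict[str, int]
    total_length: dict[str, int]
    odds_ratio: dict[str, float] = field(default_factory=dict)
    infinite: set[str] = field(default_factory=set)  # flagged sentinel ORs


def feature_odds_ratio(
    n_clusters: dict[str, int], total_length: dict[str, int]
) -> FeatureEnrichment:
    """OR_f = (n_f / L_f) / ((N - n_f) / (L - L_f)).

    The numerator is the cluster density inside feature class f, the
    denominator the density over the remaining classes. OR is invariant to
    rescaling all lengths. Features with every cluster (N - n_f = 0) get an
    infinite OR recorded in ``infinite``.
    """
    features = sorted(total_length)
    N = sum(n_clusters.get(f, 0) for f in features)
    L = sum(total_length[f] for f in features)
    result = FeatureEnrichment(
        n_clusters={f: n_clusters.get(f, 0) for f in features},
        total_length=dict(total_length),
    )
    for f in features:
        Lf = total_length[f]
        if Lf <= 0:
            raise ValueError(f"feature {f!r} has non-positive total length")
        nf = n_clusters.get(f, 0)
        rest_density_num = N - nf
        rest_len = L - Lf
        if rest_len <= 0:
            raise ValueError("odds ratio needs at least two feature classes")
        if rest_density_num == 0:
            result.odds_ratio[f] = math.inf
            result.infinite.add(f)
        else:
            result.odds_ratio[f] = (nf / Lf) / (rest_density_num / rest_len)
    return result


def classify_and_enrich(
    cluster_gene_pairs: list[tuple[SiRNACluster, GeneModel]],
    genes: list[GeneModel],
    features: tuple[str, ...] = FEATURE_PRIORITY,
) -> tuple[dict[str, str], FeatureEnrichment]:
    """Classify each (cluster, host gene) pair and compute enrichment.

    Feature lengths are summed over the representative transcripts of all
    annotated genes. Clusters labeled "other_genic" are classified but do
    not enter the odds ratios. Returns ({cluster_id: label}, enrichment).
    """
    from .annotation import total_feature_lengths

    labels = {c.cluster_id: classify_cluster_feature(c, g) for c, g in cluster_gene_pairs}
    lengths = total_feature_lengths(genes)
    lengths = {f: lengths.get(f, 0) for f in features if lengths.get(f, 0) > 0}
    counts: dict[str, int] = {}
    for lab in labels.values():
        if lab in lengths:
            counts[lab] = counts.get(lab, 0) + 1
    return labels, feature_odds_ratio(counts, lengths)


@dataclass
class ChromPositionProfile:
    """Relative arm positions (0 = centromere edge, 1 = chromosome end)."""

    positions: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray  # sums to 1 over bins
    n_in_centromere: int = 0


def chrom_position_profile(
    clusters: list[SiRNACluster], layout: GenomeLayout, n_bins: int = 20
) -> ChromPositionProfile:
    """Profile cluster midpoints along chromosome arms.

    The arm is chosen by which side of the centromere the midpoint lies;
    position = distance from the centromere edge divided by arm length.
    Midpoints inside the centromere get position 0 and are counted in
    ``n_in_centromere``.
    """
    positions = []
    n_cen = 0
    for c in clusters:
        chrom = c.interval.chrom
        if chrom not in layout.chrom_sizes or chrom not in layout.centromeres:
            raise ValueError(f"chromosome {chrom!r} missing size or centromere entry")
        size = layout.chrom_sizes[chrom]
        cen = layout.centromeres[chrom]
        mid = c.interval.midpoint()
        if cen.start <= mid < cen.end:
            n_cen += 1
            positions.append(0.0)
        elif mid < cen.start:
            positions.append((cen.start - mid) / cen.start)
        else:
            arm = size - cen.end
            positions.append((mid - cen.end) / arm)
    pos = np.asarray(positions, float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(pos, bins=edges)
    density = hist / hist.sum() if hist.sum() else hist.astype(float)
    return ChromPositionProfile(
        positions=pos, bin_edges=edges, density=density, n_in_centromere=n_cen
    )


def write_enrichment_tsv(enrichment: FeatureEnrichment, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tn_clusters\ttotal_length_bp\todds_ratio\n")
        for f in sorted(enrichment.total_length):
            orv = enrichment.odds_ratio.get(f, float("nan"))
            or_str = "inf" if math.isinf(orv) else f"{orv:.4f}"
            fh.write(
                f"{f}\t{enrichment.n_clusters.get(f, 0)}\t{enrichment.total_length[f]}\t{or_str}\n"
            )


def write_position_profile_tsv(profile: ChromPositionProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tdensity\n")
        for lo, hi, d in zip(profile.bin_edges[:-1], profile.bin_edges[1:], profile.density):
            fh.write(f"{lo:.3f}\t{hi:.3f}\t{d:.6f}\n")
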