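"""Where do siRNA clusters sit within gene bodies?

Classifies clusters by the sub-feature (intron / CDS / UTR) they overlap
most and reports length-normalized enrichment odds ratios, plus the
chromosomal positioning of clusters between centromere (0) and telomere
(1). Placement here is deliberately intron-biased (50% of clusters) to
show the intron-dominant pattern.
"""

from sirnaclust import SimulationConfig
from sirnaclust.cluster import SiRNACluster
from sirnaclust.enrichment import chrom_position_profile, classify_and_enrich
from sirnaclust.intervals import IntervalIndex
from sirnaclust.simulate import place_random_clusters, simulate_annotation

cfg = SimulationConfig(seed=1)
genes, layout = simulate_annotation(cfg)

weights = {"intron": 0.5, "cds": 0.25, "five_prime_utr": 0.125, "three_prime_utr": 0.125}
intervals = place_random_clusters(genes, 1000, seed=1, feature_weights=weights)

index = IntervalIndex()
for g in genes:
    index.add(g.body, payload=g)
pairs = [
    (SiRNACluster(f"c{i}", iv), index.overlapping_items(iv)[0][1])
    for i, iv in enumerate(intervals)
]
labels, enr = classify_and_enrich(pairs, genes)

print("feature        n_clusters  total_bp   odds_ratio")
for f in sorted(enr.odds_ratio):
    print(f"{f:<15}{enr.n_clusters[f]:>9}{enr.total_length[f]:>11}{enr.odds_ratio[f]:>12.3f}")
# The odds ratio is the per-bp cluster density inside a feature class
# relative to the density elsewhere; introns score highest because half
# of all clusters sit in well under half of the feature bp.

clusters = [c for c, _ in pairs]
profile = chrom_position_profile(clusters, layout)
print(f"\nmean relative arm position: {profile.positions.mean():.3f} "
      "(0 = centromere edge, 1 = chromosome end)")
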