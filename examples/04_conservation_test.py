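"""Are intronic siRNA cluster regions evolutionarily conserved?

Tiles UTR and intron intervals with 25-nt bins, averages a per-base
conservation track over each bin, labels bins by cluster overlap, and
runs the size-matched resampled Welch t-test (1000 draws of non-cluster
bins). The simulated track carries a +0.3 score uplift only inside
intronic planted clusters, so only the intron feature should test
significant.
"""

from sirnaclust import SimulationConfig, simulate_dataset
from sirnaclust.cluster import SiRNACluster
from sirnaclust.conservation import (
    bin_feature_regions,
    conservation_tests,
    cumulative_score_distribution,
    label_cluster_bins,
    score_bins,
)

ds = simulate_dataset(SimulationConfig(seed=1))
clusters = [SiRNACluster(c.cluster_id, c.interval) for c in ds.truth.clusters]

bins = bin_feature_regions(ds.genes, bin_size=25)
score_bins(bins, ds.track)
label_cluster_bins(bins, clusters)

results = conservation_tests(bins, n_resamples=1000, seed=1)
print("feature          cluster_bins  median_p   frac(p<=0.05)  significant")
for f, r in sorted(results.items()):
    print(f"{f:<18}{r.n_cluster_bins:>10}{r.median_p:>11.2e}{r.fraction_significant:>12.3f}"
          f"{str(r.significant):>13}")
# A feature is called significant when >= 95% of the 1000 size-matched
# resamples reject at p <= 0.05; the uplift is confined to introns, so
# UTR fractions stay near the 5% type-I level.

intron_bins = [b for b in bins if b.feature == "intron"]
table = cumulative_score_distribution(intron_bins)
print("\ncumulative fraction of intronic bins by score threshold:")
print(table.round(3).to_string(index=False))
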