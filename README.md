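# sirnaclust

Detection and evolutionary analysis of siRNA clusters in small-RNA
alignment data.

## The problem

Under short-term stress (the motivating system is drought-stressed rice
sampled at 0, 1 and 6 hours after treatment, in a drought-susceptible wild
type and two tolerant lines), plants transcribe large, heterogeneous
populations of 18–30 nt small interfering RNAs dominated by 21 and 24 nt
classes. Individually these reads are noisy; their regulatory signal
appears as dense genomic *clusters*, frequently inside the introns of the
genes they appear to repress. `sirnaclust` is a library for the full
analysis around that observation:

1. **Preprocess** aligned small-RNA reads: drop reads matching known
   miRNA/rRNA/tRNA/snoRNA sequences (exact, strand-aware substring match),
   keep 18–30 nt reads with 0 mismatches and ≤ 5 mapping sites, and
   normalize counts to reads per million (RPM), weighting a read with
   *n* mapping sites by 1/*n*.
2. **Detect clusters** with one-dimensional DBSCAN over read start
   coordinates: a read is a core point when ≥ *minpts* reads start within
   *ε* bp of it; clusters are ε-chains of core points plus reachable
   border reads. *ε* is selected at the valley (knee) of the sorted
   *k*-dist curve — the distance of each read to its *k*-th nearest
   neighbour — and defaults follow *ε* = 100 nt, *minpts* = 10, *k* = 30,
   so any reported cluster holds ≥ 10 reads over ≥ ~100 nt. Clusters are
   detected per sample and merged (≥ 1 bp overlap) per plant.
3. **Associate clusters with target genes** — genes whose bodies embody
   them — summing multi-cluster expression per gene, and quantify the
   coupling of cluster RPM and gene FPKM as log2 fold changes over
   consecutive time intervals, summarized by Pearson *r* and
   sign-quadrant counts.
4. **Measure feature enrichment** as a length-normalized odds ratio
   OR_f = (n_f / L_f) / ((N − n_f) / (L − L_f)): the per-bp cluster
   density in feature class *f* (intron, CDS, 5'/3' UTR) relative to the
   density elsewhere, plus cluster positioning along chromosome arms
   between centromere (0) and telomere (1).
5. **Test conservation**: tile UTR/intron intervals with 25-nt bins,
   average a per-base conservation-probability track (phastCons-style,
   in [0, 1]) over each bin, label bins by cluster overlap, and compare
   cluster vs non-cluster bins with Welch's two-sided t-test repeated
   over 1000 size-matched random draws of non-cluster bins; a feature is
   called significant when ≥ 95% of draws reject at p ≤ 0.05.

A first-class synthetic-data module (`sirnaclust.simulate`) generates the
whole input bundle — annotation, nine read libraries, expression table,
conservation track, filter FASTA — with planted ground truth, so every
stage is testable without external downloads.

## Worked example

```bash
python examples/01_simulate_and_detect.py
```

```
WT 0h library: 11835 alignments, modal lengths [24, 21] nt
detected 20 merged clusters vs 20 planted
precision 1.000  recall 1.000  F1 1.000
  WT_m00000: chr1:47353-47644  reads/sample [35.0, 98.0, 119.0]
  ...
```

The library keeps the expected bimodal 21/24-nt length profile after
filtering; DBSCAN at ε = 100/minpts = 10 recovers all 20 planted clusters
(each ≥ 80% covered by exactly one detected cluster) with no spurious
background clusters. The other examples each cover one capability:

- `02_expression_correlation.py` — recovers the planted gene-vs-cluster
  fold-change correlation of −0.8 (prints `WT: r = -0.794 … 752/1000
  points in the anticorrelated quadrants`);
- `03_feature_enrichment.py` — length-normalized odds ratios with
  intron-biased placement (intron OR 1.700, the maximum);
- `04_conservation_test.py` — the resampled t-test finds the intron-only
  conservation uplift (intron fraction significant 1.000, UTRs ≈ 0.05)
  and prints the cumulative score distribution of intronic bins;
- `05_full_pipeline.py` — `run_all` from one config, with a manifest of
  per-stage counts and byte-identical reruns.

A thin CLI wraps the same functions:

```bash
sirnaclust simulate --seed 1 --out data/
sirnaclust cluster --reads data/reads_WT_0.bed --auto --k 30 --out clusters.bed
sirnaclust run-all --config config.yaml --out results/
```

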