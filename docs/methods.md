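# Methods

This note documents the models, parameters and design choices behind
`sirnaclust`, what the synthetic data does and does not emulate, and the
numerical conventions used throughout.

## Coordinates and annotation model

All internal coordinates are 0-based half-open `[start, end)`; GFF3
(1-based inclusive) is converted at the I/O boundary, BED is passed
through unchanged. Overlap always means ≥ 1 shared base, so book-ended
intervals do not overlap or merge.

Each gene is reduced to one *representative transcript* — the
longest-spanning mRNA, ties broken by lexicographically smallest
transcript id — from which sub-features are derived: introns are the gaps
between consecutive exons; 5'/3' UTRs are the exonic sequence up/downstream
of the CDS extent in transcript orientation (strand-aware). Genes without
CDS records contribute no UTR features. The gene *body* is the full gene
span including introns, because cluster–gene association asks whether a
gene embodies a cluster anywhere in its body. Multi-isoform feature unions
are out of scope; the representative-transcript convention is ours, since
isoform handling is genuinely open in this analysis design.

## Preprocessing

- Retention filter: 18 ≤ length ≤ 30 nt, mismatches ≤ 0, mapping sites
  ≤ 5 (all boundaries inclusive).
- ncRNA filter: a read is removed iff its sequence is an exact substring
  of any filter-set sequence on either strand; removal is by read id, so
  all alignments of a matched read drop. Matching is on sequence, not
  coordinates, mirroring "perfectly maps to" a database entry. Reads
  without sequences pass through with a warning.
- RPM normalization: count × 10⁶ / total processed reads. "Processed" is
  ambiguous between before and after filtering; the default denominator
  is the **post-filter** weighted total (making per-sample siRNA
  abundances directly comparable), with `denominator="pre_filter"`
  available.
- Multi-mapping: each alignment of a read with *n* sites contributes
  weight 1/*n* to any count (`weighting="full"` disables this). The
  source analyses keep ≤ 5-site reads without stating a counting rule;
  fractional weighting avoids over-counting.

## Cluster detection

Reads are points at their leftmost mapped coordinate; distance is the
absolute difference of start coordinates. DBSCAN core condition: ≥
*minpts* points (self included) within *ε*. Clusters are connected
components of core points under ε-reachability; a border (non-core) point
joins the cluster of the **leftmost** core point within ε of it — a
documented, deterministic tie-break that makes output invariant to input
order. Noise points belong to no cluster.

Two spans are reported per cluster: the full member hull (leftmost member
start to rightmost member end) and the `core_span` (hull of core points
only). Border reads — and background reads close enough to a dense edge
to become core — stretch the full hull by up to ε per side *by
construction*, so recovery scoring against planted regions uses coverage
of the planted interval (≥ 80% by default) rather than interval Jaccard,
which would measure boundary sharpness rather than detection. Strict
Jaccard matching remains available (`criterion="jaccard"`).

Epsilon selection: the k-dist profile (distance of each read to its
*k*-th nearest neighbour, ties by distance only) is sorted descending and
both axes min-max normalized; *ε* is the value at the point of maximum
perpendicular distance to the chord joining the endpoints (the knee /
valley), ties to the smallest index. A uniform profile has no valley and
raises an error; a knee at an endpoint-adjacent index, or a maximum chord
distance below 1% of the normalized scale (a near-linear profile), is
flagged low-confidence. Defaults *ε* = 100 nt, *minpts* = 10, *k* = 30;
`auto_minpts` sets *minpts* = *k* for the variant in which the
neighbour rank doubles as the density threshold — both readings of the
parameter coupling are kept because the intended relation between *k*
and *minpts* is ambiguous in the underlying method description. When
parameters are fitted automatically, they are fitted once on the first
sample (wild type, 0 h) and reused across all libraries.

Per-sample clusters are merged per plant by transitive ≥ 1 bp overlap;
merged intervals are union hulls with per-sample counts/RPM summed. No
minimum-span post-filter is applied by default — the ≥ ~100 nt span is a
consequence of the parameters, not a filter — `min_span` is available.

## Cluster–gene association and correlation

Genes whose FPKM never strictly exceeds 1 at any of the plant's time
points are removed ("not exceeding" read as strict, so a flat 1.0 profile
drops). A merged cluster targets the gene containing it; because merging
can push hulls past gene edges, a straddling cluster is still assigned
when ≥ 50% of its length lies in the body (largest-overlap gene wins,
ties by gene id); `strict_containment` restores pure containment. Clusters
matching no gene are intergenic and excluded. Clusters of a common target
gene are pooled by summing expression, giving one pair per gene.

Fold changes are log2((b + 1)/(a + 1)) with pseudocount 1.0 on both RPM
and FPKM (zero-handling is not specified by the source analysis; the
shared pseudocount preserves antisymmetry). Pearson r uses the standard
product-moment estimate with a t-distribution p-value; zero-variance
input is flagged and reported as NaN. The correlation report emits per
pair and per interval (0→1 h, 1→6 h) the two fold changes, the pooled r
and p, and sign-quadrant counts; points on an axis (either fold change
exactly zero) are counted separately rather than forced into a quadrant.

## Feature enrichment and chromosome positioning

A genic cluster is classified by maximal bp overlap among intron, CDS,
5'UTR, 3'UTR (ties broken in that priority order; zero overlap with all
four ⇒ `other_genic`). Enrichment per feature class is the density ratio
OR_f = (n_f / L_f) / ((N − n_f) / (L − L_f)) with lengths summed over all
genes' representative transcripts; the "odds ratio" is named but not
defined in the source analysis, and the density-ratio form is adopted
because it is scale-invariant and directly answers "are clusters denser
here than elsewhere, per bp". N − n_f = 0 yields an infinite OR reported
as a flagged sentinel. Chromosome positioning uses cluster midpoints
(spans are negligible at chromosome scale): position = distance from the
centromere edge divided by arm length, arm chosen by which side of the
centromere the midpoint lies; midpoints inside the centromere are flagged
and assigned 0.

## Conservation testing

Only 5'UTR, 3'UTR and intron intervals are binned; CDS is excluded up
front because its uniformly high conservation dominates any comparison.
Bins are 25 nt, anchored at each feature interval's left edge, remainders
< 25 nt dropped (no genome-global grid; the anchoring convention is
unspecified upstream and left-edge anchoring is the simplest reproducible
choice). A bin's score is the mean track value over present bases; bins
with < 50% of bases covered are excluded from testing. A bin is a cluster
bin iff it overlaps a merged cluster by ≥ 1 bp.

Because cluster bins are much rarer than non-cluster bins, each test
draws |cluster bins| non-cluster bins without replacement and applies
Welch's two-sided t-test (pooled-variance Student's variant behind
`equal_var=True`), repeated 1000 times with a seeded generator. The 1000
p-values are summarized by their median and by the fraction ≤ α = 0.05;
a feature is called significant when that fraction is ≥ 0.95
(configurable). How the original analysis aggregated its 1000 p-values is
not stated; median-plus-fraction makes both the location and the
stability of the result explicit. Resamples with zero variance in both
groups and equal means have no t statistic; they count as non-significant
(p = 1) and are tallied in `n_degenerate`. The test consumes a per-base
track in reference coordinates; projecting scores from multiple-sequence
alignments of orthologs into those coordinates is upstream of this
package.

Candidate selection for downstream motif work keeps pairs whose gene and
cluster fold changes have strictly opposite signs in at least one
interval and whose gene has orthologs in ≥ 4 species including the
reference; cluster sequences are exported as plus-strand FASTA.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: three plants × three time
points, one library each, 18–30 nt reads with a categorical length
distribution peaking at 24 nt then 21 nt. Defaults define the test
conditions used throughout: a 2 Mbp, 2-chromosome genome with 50
non-overlapping multi-exon genes; 20 planted clusters of 120–300 bp with
≥ 10 reads per sample (so every planted cluster is detectable by
construction), hosted 60% in introns and 20% in each UTR; uniform
background at 5 reads/kbp/sample, 2% of background reads with
out-of-range lengths to exercise the length filter; 100 contaminant reads
per sample whose sequences are verbatim substrings of a generated filter
FASTA. Gene geometry is rice-like — short introns (150–450 bp), so intron
bp is a minority of the gene body even though introns outnumber UTRs —
which is what makes intron-biased cluster placement register as
length-normalized enrichment.

Expression coupling: for each planted cluster, plant and time interval, a
(gene, cluster) pair of log2 fold changes is drawn from a bivariate
normal with standard deviation 1.5 and correlation ρ (default −0.8);
cluster read counts follow the cluster trajectory exactly (rounded,
floored at 10), host-gene FPKM follows the gene trajectory from a 50–200
FPKM baseline (high enough that the +1 pseudocount attenuates the
recovered correlation by ≲ 0.03). Non-host genes move independently; two
genes are planted flat at 0.5 FPKM to exercise the floor filter.
Conservation: per-base scores are Gaussian noise (sd 0.1) around
feature-specific baselines (intron 0.25, 3'UTR 0.40, 5'UTR 0.45 — UTRs
more conserved than introns, as in real genomes), clipped to [0, 1], with
+0.3 added inside intronic planted clusters only; bases outside
UTR/intron features are left missing, since the analysis never reads
them.

Not emulated: read sequences for non-contaminant reads (the pipeline
starts from alignments), sequencing error, multi-mapping structure (all
simulated reads have one site; fractional weighting is exercised by unit
tests), repeat-driven cluster formation, isoform diversity, and any
realistic genome sequence. Passing tests therefore demonstrate that the
algorithms recover planted structure under the stated statistical
conditions, not that real rice libraries would yield these exact
patterns.

All generator stages draw from fixed, independent child streams of one
root seed, so identical configs produce byte-identical output files.

## Verification scale and calibration conventions

Clustering primitives are verified against independent all-pairs
reference implementations (k-dist and DBSCAN, including the border
tie-break) on 100 random instances of up to 500 reads. Detection recovery
is scored on the default conditions above; one-to-one matching by ≥ 80%
coverage of the planted interval (see the cluster-detection section for
why coverage, not Jaccard). The resampled conservation test is calibrated
under the null by averaging the significant-resample fraction over 50
outer seeds (observed ≈ 0.05) and its power checked with a +0.3 shift at
noise sd 0.1 and 100 cluster bins (fraction ≥ 0.99). Enrichment
calibration averages per-feature odds ratios over 10 independent draws of
1000 uniformly placed clusters: a single draw of 1000 carries multinomial
noise of sd ≈ 0.07–0.10 per feature, so calibration — means near 1.0 — is
asserted on the replicate average, with a wide per-draw sanity envelope.
The epsilon-selection check plants clusters with exact 3-bp read spacing
among sparse noise, where the k-dist valley has a known admissible range.
End-to-end runs use a reduced genome (0.4–2 Mbp) so the full suite
completes in well under a minute of compute per scenario; problem sizes
are stated alongside each reported quantity by `scripts/acceptance.py`.

## Known limitations

- Border-point assignment is a convention; other DBSCAN implementations
  may attach shared border points to a different neighbouring cluster.
- The knee heuristic assumes a two-regime (sparse background / dense
  cluster) k-dist curve; heavy-tailed spacing distributions can produce
  low-confidence selections that should be inspected via the exported
  profile.
- Feature lengths for enrichment count representative transcripts only;
  genes with isoform-specific introns contribute a single structure.
- The conservation test treats bins as independent; adjacent 25-nt bins
  of one cluster share local sequence context, so the effective sample
  size is smaller than the bin count. The size-matched resampling
  addresses group imbalance, not autocorrelation.
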