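"""Ground-truth-annotated synthetic inputs for the whole pipeline.

The generator emulates the drought time-course design: three plants (a
drought-susceptible wild type and two tolerant lines) sampled at 0, 1 and
6 hours after treatment, each sample a library of aligned 18-30 nt reads
with the characteristic bimodal 21/24-nt length profile. Dense siRNA
clusters are planted inside gene sub-features (mostly introns) on a
non-overlapping synthetic gene annotation; background reads fall uniformly
over the genome at a configurable rate. Host-gene FPKM series and planted
cluster read counts move together as correlated log2 fold changes (the
default correlation is negative, mirroring the siRNA-up / gene-down
coupling the analysis is designed to expose), and a conservation track
gives intronic planted clusters a configurable score uplift.

Everything is deterministic given the seed, and the ground-truth record is
sufficient to score detection precision/recall on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, build_gene_model, write_gff3
from .conservation import ConservationTrack
from .intervals import GenomeLayout, GenomicInterval
from .preprocess import READ_COLUMNS, sample_label

DEFAULT_READ_LENGTH_DIST = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.25, 22: 0.06, 23: 0.05,
    24: 0.35, 25: 0.06, 26: 0.04, 27: 0.03, 28: 0.02, 29: 0.02, 30: 0.01,
}

DEFAULT_FEATURE_BASELINE = {
    "intron": 0.25,
    "five_prime_utr": 0.45,
    "three_prime_utr": 0.40,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation settings.

    Defaults describe the conditions the pipeline is meant to recover:
    a 2 Mbp two-chromosome genome carrying 50 genes, 20 planted clusters
    (span >= ~120 bp, >= 10 reads per sample) hosted mostly in introns,
    background of 5 reads/kbp/sample, 21/24-nt biased lengths, a gene vs
    cluster log2-FC correlation of -0.8, and a +0.3 conservation uplift at
    sd 0.1 confined to intronic planted clusters.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 50
    n_planted_clusters: int = 20
    cluster_feature_weights: tuple[tuple[str, float], ...] = (
        ("intron", 0.6),
        ("five_prime_utr", 0.2),
        ("three_prime_utr", 0.2),
    )
    cluster_span_range: tuple[int, int] = (120, 300)
    cluster_base_reads_range: tuple[int, int] = (60, 150)
    log2fc_sd: float = 1.5
    anticorrelation_rho: float = -0.8
    background_rate: float = 5.0  # expected background reads per kbp per sample
    out_of_range_fraction: float = 0.02  # background reads with lengths outside 18-30
    read_length_dist: tuple[tuple[int, float], ...] = tuple(DEFAULT_READ_LENGTH_DIST.items())
    plants: tuple[str, ...] = ("WT", "ap2", "Vandana")
    time_points: tuple[int, ...] = (0, 1, 6)
    n_filter_seqs: int = 6
    n_contaminant_reads: int = 100  # per sample; sequences drawn verbatim from the filter FASTA
    gene_fpkm_range: tuple[float, float] = (50.0, 200.0)
    n_silent_genes: int = 2  # genes planted below the 1-FPKM floor
    cluster_strand_mix: float = 0.5
    conservation_effect: float = 0.3
    conservation_noise_sd: float = 0.1
    feature_baseline: tuple[tuple[str, float], ...] = tuple(DEFAULT_FEATURE_BASELINE.items())

    def __post_init__(self) -> None:
        if not (-1.0 <= self.anticorrelation_rho <= 0.0):
            raise ValueError("anticorrelation_rho must lie in [-1, 0]")
        dist = dict(self.read_length_dist)
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("read_length_dist must sum to 1")
        if not set(dist) <= set(range(18, 31)):
            raise ValueError("read_length_dist support must lie in [18, 30]")
        if self.cluster_span_range[0] < 100:
            raise ValueError("planted cluster span must be >= 100 bp")
        if self.conservation_effect < 0:
            raise ValueError("conservation_effect must be >= 0")

    @property
    def length_dist(self) -> dict[int, float]:
        return dict(self.read_length_dist)

    @property
    def feature_weights(self) -> dict[str, float]:
        return dict(self.cluster_feature_weights)

    @property
    def baselines(self) -> dict[str, float]:
        return dict(self.feature_baseline)

    @property
    def samples(self) -> list[tuple[str, int]]:
        return [(p, t) for p in self.plants for t in self.time_points]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_mapping(cls, data: dict) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        coerced = dict(data)
        for key in (
            "cluster_feature_weights", "read_length_dist", "feature_baseline",
        ):
            if key in coerced and isinstance(coerced[key], dict):
                coerced[key] = tuple(coerced[key].items())
            elif key in coerced:
                coerced[key] = tuple(tuple(x) for x in coerced[key])
        for key in ("cluster_span_range", "cluster_base_reads_range", "gene_fpkm_range"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        for key in ("plants", "time_points"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)


@dataclass
class PlantedCluster:
    """Ground truth for one planted cluster."""

    cluster_id: str
    gene_id: str
    feature: str
    interval: GenomicInterval
    counts: dict[str, int]  # sample label -> planted read count
    gene_log2fc: dict[str, dict[str, float]]  # plant -> interval label -> target FC


@dataclass
class GroundTruth:
    clusters: list[PlantedCluster]
    rho: float
    conservation_effect: float

    def uplift_intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.clusters if c.feature == "intron"]

    def to_json(self, path: str | Path) -> None:
        data = {
            "rho": self.rho,
            "conservation_effect": self.conservation_effect,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "gene_id": c.gene_id,
                    "feature": c.feature,
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "counts": c.counts,
                    "gene_log2fc": c.gene_log2fc,
                }
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        clusters = [
            PlantedCluster(
                cluster_id=c["cluster_id"],
                gene_id=c["gene_id"],
                feature=c["feature"],
                interval=GenomicInterval(c["chrom"], c["start"], c["end"]),
                counts={k: int(v) for k, v in c["counts"].items()},
                gene_log2fc=c["gene_log2fc"],
            )
            for c in data["clusters"]
        ]
        return cls(
            clusters=clusters,
            rho=data["rho"],
            conservation_effect=data["conservation_effect"],
        )


# fixed child-stream indices so every stage has an independent, stable stream
_STREAM = {
    "annotation": 0,
    "clusters": 1,
    "filter_fasta": 2,
    "expression": 3,
    "conservation": 4,
    "genome_fasta": 5,
    # read libraries use 16 + sample index
}


def _child_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    root = np.random.SeedSequence(config.seed)
    return np.random.default_rng(root.spawn(index + 1)[index])


def _simulate_gene(rng: np.random.Generator, chrom: str, start: int, strand: str, gene_id: str) -> GeneModel:
    n_exons = int(rng.integers(3, 6))
    utr5 = int(rng.integers(180, 320))
    utr3 = int(rng.integers(220, 420))
    exon_lens = [utr5 + int(rng.integers(100, 200))]
    exon_lens += [int(rng.integers(150, 400)) for _ in range(n_exons - 2)]
    exon_lens.append(utr3 + int(rng.integers(100, 200)))
    # rice-like geometry: introns mostly short, so intron bp is a minority
    # of the gene body even though introns outnumber UTRs
    intron_lens = [int(rng.integers(150, 450)) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    body = GenomicInterval(chrom, start, exons[-1].end, strand)
    # CDS: transcript minus terminal UTR stretches (strand-aware)
    left_trim, right_trim = (utr5, utr3) if strand == "+" else (utr3, utr5)
    cds = []
    for e in exons:
        lo = e.start + (left_trim if e is exons[0] else 0)
        hi = e.end - (right_trim if e is exons[-1] else 0)
        if lo < hi:
            cds.append(GenomicInterval(chrom, lo, hi, strand))
    return build_gene_model(gene_id, body, exons, cds, transcript_id=f"{gene_id}.t1")


def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], GenomeLayout]:
    """Generate a non-overlapping multi-exon gene annotation plus layout.

    Every gene has >= 2 introns, CDS and both UTRs; genes are placed
    uniformly (non-overlapping) along the chromosomes, round-robin across
    chromosomes. Centromeres occupy the central 4% of each chromosome.
    """
    rng = _child_rng(config, _STREAM["annotation"])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    cen_half = max(int(config.chrom_length * 0.02), 1)
    centromeres = {
        c: GenomicInterval(c, config.chrom_length // 2 - cen_half, config.chrom_length // 2 + cen_half)
        for c in chroms
    }
    layout = GenomeLayout(chrom_sizes=sizes, centromeres=centromeres)
    if config.n_genes == 0:
        return [], layout

    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]].append(f"gene_{i + 1:04d}")

    genes: list[GeneModel] = []
    max_span = 2 * (420 + 200) + 3 * 400 + 4 * 450  # loose upper bound on a gene span
    for chrom in chroms:
        ids = per_chrom[chrom]
        if not ids:
            continue
        slack = config.chrom_length - len(ids) * max_span
        if slack <= len(ids):
            raise ValueError(
                f"infeasible packing: {len(ids)} genes do not fit in {config.chrom_length} bp"
            )
        offsets = np.sort(rng.choice(slack, size=len(ids), replace=False))
        cursor = 0
        for gene_id, off in zip(ids, offsets):
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _simulate_gene(rng, chrom, int(off) + cursor, strand, gene_id)
            genes.append(gene)
            cursor += gene.body.length() + 1
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    return genes, layout


def plant_clusters(config: SimulationConfig, genes: list[GeneModel]) -> GroundTruth:
    """Choose host features and plant ground-truth clusters with correlated
    gene/cluster expression trajectories.

    For each planted cluster, plant and time interval, a (gene, cluster)
    pair of log2 fold changes is drawn from a bivariate normal with
    correlation ``anticorrelation_rho``; cluster read counts follow the
    cluster trajectory exactly (floored at 10 reads per sample so every
    planted cluster stays detectable).
    """
    rng = _child_rng(config, _STREAM["clusters"])
    if config.n_planted_clusters == 0:
        return GroundTruth([], config.anticorrelation_rho, config.conservation_effect)
    if not genes:
        raise ValueError("cannot plant clusters without genes")
    span_lo, span_hi = config.cluster_span_range
    weights = config.feature_weights
    labels = list(weights)
    probs = np.array([weights[l] for l in labels], float)
    probs = probs / probs.sum()

    replace = config.n_planted_clusters > len(genes)
    host_idx = rng.choice(len(genes), size=config.n_planted_clusters, replace=replace)
    sd = config.log2fc_sd
    cov = sd**2 * np.array([[1.0, config.anticorrelation_rho], [config.anticorrelation_rho, 1.0]])

    clusters: list[PlantedCluster] = []
    for ci, gi in enumerate(host_idx):
        gene = genes[int(gi)]
        order = rng.permutation(len(labels))
        chosen_iv = None
        chosen_label = None
        # feature drawn by weight, falling back to any feature long enough
        for li in list(rng.choice(len(labels), size=8, p=probs)) + list(order):
            label = labels[int(li)]
            candidates = [iv for iv in gene.feature_intervals(label) if iv.length() >= span_lo + 4]
            if candidates:
                chosen_label = label
                chosen_iv = candidates[int(rng.integers(len(candidates)))]
                break
        if chosen_iv is None:
            raise ValueError(f"gene {gene.gene_id} has no feature long enough to host a cluster")
        span = int(rng.integers(span_lo, min(span_hi, chosen_iv.length() - 2) + 1))
        offset = int(rng.integers(chosen_iv.length() - span + 1))
        interval = GenomicInterval(
            chosen_iv.chrom, chosen_iv.start + offset, chosen_iv.start + offset + span
        )

        base = int(rng.integers(*config.cluster_base_reads_range))
        counts: dict[str, int] = {}
        gene_fc: dict[str, dict[str, float]] = {}
        for plant in config.plants:
            level = float(base)
            counts[sample_label(plant, config.time_points[0])] = max(10, int(round(level)))
            gene_fc[plant] = {}
            for t0, t1 in zip(config.time_points, config.time_points[1:]):
                zg, zc = rng.multivariate_normal([0.0, 0.0], cov)
                gene_fc[plant][f"{t0}-{t1}"] = float(zg)
                level = level * 2.0**zc
                counts[sample_label(plant, t1)] = max(10, int(round(level)))
        clusters.append(
            PlantedCluster(
                cluster_id=f"planted_{ci:04d}",
                gene_id=gene.gene_id,
                feature=chosen_label,
                interval=interval,
                counts=counts,
                gene_log2fc=gene_fc,
            )
        )
    return GroundTruth(clusters, config.anticorrelation_rho, config.conservation_effect)


def _random_filter_fasta(rng: np.random.Generator, n: int) -> dict[str, str]:
    kinds = ["miRNA", "rRNA", "tRNA", "snoRNA"]
    seqs = {}
    for i in range(n):
        length = int(rng.integers(60, 90))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        seqs[f"{kinds[i % len(kinds)]}_{i:02d}"] = seq
    return seqs


def simulate_filter_fasta(config: SimulationConfig) -> dict[str, str]:
    rng = _child_rng(config, _STREAM["filter_fasta"])
    return _random_filter_fasta(rng, config.n_filter_seqs)


def simulate_reads(
    config: SimulationConfig,
    layout: GenomeLayout,
    truth: GroundTruth,
    filter_seqs: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate one aligned-read library per plant x time point.

    Planted reads start uniformly inside their cluster span with counts
    matching the ground truth exactly; background reads are Poisson at
    ``background_rate`` per kbp, uniform over the genome, a small fraction
    with out-of-range lengths (exercising the 18-30 nt filter). Contaminant
    reads carry sequences copied verbatim from the filter FASTA so the
    ncRNA filter removes exactly them. All records have mismatches = 0 and
    n_sites = 1.
    """
    rngs = [_child_rng(config, 16 + i) for i in range(len(config.samples))]
    if filter_seqs is None and config.n_contaminant_reads > 0:
        filter_seqs = simulate_filter_fasta(config)
    chroms = sorted(layout.chrom_sizes)
    chrom_arr = np.array(chroms)
    sizes = np.array([layout.chrom_sizes[c] for c in chroms], float)
    lengths_support = np.array(sorted(config.length_dist))
    lengths_p = np.array([config.length_dist[l] for l in lengths_support])

    libraries: dict[str, pd.DataFrame] = {}
    for (plant, t), rng in zip(config.samples, rngs):
        label = sample_label(plant, t)
        rows = []
        rid = 0
        for pc in truth.clusters:
            n = pc.counts[label]
            lens = rng.choice(lengths_support, size=n, p=lengths_p)
            lo = pc.interval.start
            hi = pc.interval.end
            starts = rng.integers(lo, np.maximum(lo + 1, hi - lens), size=n)
            strands = np.where(rng.random(n) < config.cluster_strand_mix, "+", "-")
            for s, ln, st in zip(starts, lens, strands):
                rows.append(
                    (pc.interval.chrom, int(s), int(s + ln), f"{label}_r{rid:07d}",
                     0, st, int(ln), 0, 1, None)
                )
                rid += 1
        # background
        genome_kbp = sizes.sum() / 1000.0
        n_bg = int(rng.poisson(config.background_rate * genome_kbp))
        if n_bg:
            ci = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
            lens = rng.choice(lengths_support, size=n_bg, p=lengths_p)
            oor = rng.random(n_bg) < config.out_of_range_fraction
            lens = np.where(oor, rng.choice([16, 17, 31, 32], size=n_bg), lens)
            starts = (rng.random(n_bg) * (sizes[ci] - lens)).astype(int)
            strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
            for c, s, ln, st in zip(chrom_arr[ci], starts, lens, strands):
                rows.append(
                    (str(c), int(s), int(s + ln), f"{label}_r{rid:07d}", 0, st, int(ln), 0, 1, None)
                )
                rid += 1
        # contaminants: exact substrings of filter sequences
        if filter_seqs and config.n_contaminant_reads:
            names = sorted(filter_seqs)
            for _ in range(config.n_contaminant_reads):
                src = filter_seqs[names[int(rng.integers(len(names)))]]
                ln = int(rng.integers(18, 31))
                off = int(rng.integers(len(src) - ln + 1))
                seq = src[off:off + ln]
                c = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(layout.chrom_sizes[c] - ln))
                st = "+" if rng.random() < 0.5 else "-"
                rows.append((c, s, s + ln, f"{label}_cont{rid:07d}", 0, st, ln, 0, 1, seq))
                rid += 1
        libraries[label] = pd.DataFrame(rows, columns=READ_COLUMNS)
    return libraries


def simulate_expression(config: SimulationConfig, genes: list[GeneModel], truth: GroundTruth) -> pd.DataFrame:
    """FPKM table (gene x plant_hat) whose host-gene trajectories follow the
    planted log2 fold changes; non-host genes move independently. The first
    ``n_silent_genes`` non-host genes are planted flat at 0.5 FPKM so the
    downstream 1-FPKM floor filter has work to do."""
    rng = _child_rng(config, _STREAM["expression"])
    host_fc = {}
    for pc in truth.clusters:
        host_fc.setdefault(pc.gene_id, pc.gene_log2fc)
    samples = [sample_label(p, t) for p, t in config.samples]
    data = {}
    lo, hi = config.gene_fpkm_range
    n_silent = 0
    for gene in genes:
        series = {}
        fcs = host_fc.get(gene.gene_id)
        if fcs is None and n_silent < config.n_silent_genes:
            n_silent += 1
            for s in samples:
                series[s] = 0.5
            data[gene.gene_id] = series
            continue
        for plant in config.plants:
            level = float(rng.uniform(lo, hi))
            series[sample_label(plant, config.time_points[0])] = level
            for t0, t1 in zip(config.time_points, config.time_points[1:]):
                if fcs is not None:
                    z = fcs[plant][f"{t0}-{t1}"]
                else:
                    z = float(rng.normal(0.0, config.log2fc_sd))
                level = level * 2.0**z
                series[sample_label(plant, t1)] = level
        data[gene.gene_id] = series
    table = pd.DataFrame.from_dict(data, orient="index")[samples]
    table.index.name = "gene_id"
    return table


def simulate_conservation(
    config: SimulationConfig, genes: list[GeneModel], truth: GroundTruth
) -> ConservationTrack:
    """Per-base conservation over UTR/intron feature intervals.

    Scores are clipped-to-[0,1] Gaussian noise around a feature-specific
    baseline; bases inside intronic planted clusters get an extra
    ``conservation_effect`` before clipping. Bases outside UTR/intron
    features stay missing (the analysis never reads them).
    """
    rng = _child_rng(config, _STREAM["conservation"])
    chrom_max: dict[str, int] = {}
    for gene in genes:
        chrom_max[gene.body.chrom] = max(chrom_max.get(gene.body.chrom, 0), gene.body.end)
    arrays = {c: np.full(n, np.nan) for c, n in chrom_max.items()}
    baselines = config.baselines
    for gene in genes:
        arr = arrays[gene.body.chrom]
        for label, base in baselines.items():
            for iv in gene.feature_intervals(label):
                arr[iv.start:iv.end] = base + rng.normal(
                    0.0, config.conservation_noise_sd, iv.length()
                )
    for iv in truth.uplift_intervals():
        arrays[iv.chrom][iv.start:iv.end] += config.conservation_effect
    for c in arrays:
        np.clip(arrays[c], 0.0, 1.0, out=arrays[c])
    return ConservationTrack(arrays)


def simulate_genome_fasta(config: SimulationConfig, layout: GenomeLayout, path: str | Path) -> None:
    """Random ACGT genome matching the layout (for sequence-export stages)."""
    rng = _child_rng(config, _STREAM["genome_fasta"])
    alphabet = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom in sorted(layout.chrom_sizes):
            fh.write(f">{chrom}\n")
            seq = alphabet[rng.integers(4, size=layout.chrom_sizes[chrom])]
            line = "".join(seq)
            for i in range(0, len(line), 80):
                fh.write(line[i:i + 80] + "\n")


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything one simulation produces."""

    config: SimulationConfig
    genes: list[GeneModel]
    layout: GenomeLayout
    truth: GroundTruth
    libraries: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    track: ConservationTrack
    filter_seqs: dict[str, str]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage with one config."""
    genes, layout = simulate_annotation(config)
    truth = plant_clusters(config, genes) if config.n_planted_clusters else GroundTruth(
        [], config.anticorrelation_rho, config.conservation_effect
    )
    filter_seqs = simulate_filter_fasta(config)
    libraries = simulate_reads(config, layout, truth, filter_seqs)
    expression = simulate_expression(config, genes, truth)
    track = simulate_conservation(config, genes, truth)
    return SimulatedDataset(
        config=config,
        genes=genes,
        layout=layout,
        truth=truth,
        libraries=libraries,
        expression=expression,
        track=track,
        filter_seqs=filter_seqs,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, str]:
    """Write a dataset to disk; returns {artifact: relative path}."""
    from .preprocess import write_bed_reads
    from .association import write_expression_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_gff3(ds.genes, out / "annotation.gff3", layout=ds.layout)
    paths["annotation"] = "annotation.gff3"
    ds.layout.to_tsv(out / "chrom_sizes.tsv", out / "centromeres.tsv")
    paths["chrom_sizes"] = "chrom_sizes.tsv"
    paths["centromeres"] = "centromeres.tsv"
    for label, df in ds.libraries.items():
        name = f"reads_{label}.bed"
        write_bed_reads(df, out / name)
        paths[f"reads_{label}"] = name
    write_expression_tsv(ds.expression, out / "expression.tsv")
    paths["expression"] = "expression.tsv"
    ds.track.to_bedgraph(out / "conservation.bedGraph")
    paths["conservation"] = "conservation.bedGraph"
    with open(out / "filter.fasta", "w") as fh:
        for name in sorted(ds.filter_seqs):
            fh.write(f">{name}\n{ds.filter_seqs[name]}\n")
    paths["filter_fasta"] = "filter.fasta"
    ds.truth.to_json(out / "ground_truth.json")
    paths["ground_truth"] = "ground_truth.json"
    ds.config.to_yaml(out / "config.yaml")
    paths["config"] = "config.yaml"
    return paths


def place_random_clusters(
    genes: list[GeneModel],
    n: int,
    seed: int = 0,
    feature_weights: dict[str, float] | None = None,
    span: int = 50,
    features: tuple[str, ...] = ("intron", "cds", "five_prime_utr", "three_prime_utr"),
) -> list[GenomicInterval]:
    """Drop synthetic cluster intervals onto gene sub-features.

    With ``feature_weights=None`` placement is uniform per bp over the
    pooled feature space (the null model for enrichment calibration);
    otherwise the feature class is drawn by weight first and the position
    uniformly within that class. Each placed interval of width ``span``
    lies fully inside a single feature interval.
    """
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[GenomicInterval]] = {f: [] for f in features}
    for gene in genes:
        for f in features:
            for iv in gene.feature_intervals(f):
                if iv.length() >= span:
                    by_label[f].append(iv)
    by_label = {f: ivs for f, ivs in by_label.items() if ivs}

    def draw_from(ivs: list[GenomicInterval]) -> GenomicInterval:
        # weight by full interval length so the per-bp density is uniform
        # across intervals of different sizes
        lens = np.array([iv.length() for iv in ivs], float)
        i = int(rng.choice(len(ivs), p=lens / lens.sum()))
        iv = ivs[i]
        off = int(rng.integers(iv.length() - span + 1))
        return GenomicInterval(iv.chrom, iv.start + off, iv.start + off + span)

    out = []
    if feature_weights is None:
        pool = [iv for ivs in by_label.values() for iv in ivs]
        for _ in range(n):
            out.append(draw_from(pool))
    else:
        labels = [f for f in feature_weights if f in by_label]
        probs = np.array([feature_weights[f] for f in labels], float)
        probs /= probs.sum()
        for _ in range(n):
            f = labels[int(rng.choice(len(labels), p=probs))]
            out.append(draw_from(by_label[f]))
    return out


def evenly_spaced_cluster_positions(
    n_clusters: int,
    reads_per_cluster: int,
    spacing: int,
    genome_length: int,
    n_noise: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Read start positions with fixed within-cluster spacing plus sparse noise.

    Clusters are placed at evenly separated anchors; every cluster holds
    ``reads_per_cluster`` starts exactly ``spacing`` bp apart. Returns
    (positions, planted (start, end) spans). Used to exercise k-dist-driven
    epsilon selection where the in-cluster spacing is known.
    """
    rng = np.random.default_rng(seed)
    span = spacing * (reads_per_cluster - 1)
    gap = genome_length // (n_clusters + 1)
    if gap <= span:
        raise ValueError("clusters do not fit the genome length")
    positions = []
    spans = []
    for i in range(n_clusters):
        anchor = gap * (i + 1)
        starts = anchor + spacing * np.arange(reads_per_cluster)
        positions.append(starts)
        spans.append((int(starts[0]), int(starts[-1] + 1)))
    noise = rng.integers(0, genome_length, size=n_noise)
    positions.append(noise)
    return np.sort(np.concatenate(positions)), spans
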