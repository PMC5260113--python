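"""End-to-end orchestration: preprocess -> cluster -> associate -> enrich ->
conserve -> export, with a manifest recording configuration hash, seeds and
per-stage record counts. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import association, cluster, conservation, enrichment, preprocess
from .annotation import read_gff3
from .intervals import GenomeLayout
from .simulate import SimulationConfig, simulate_dataset, simulate_genome_fasta, write_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PreprocessSettings:
    min_len: int = 18
    max_len: int = 30
    max_mismatch: int = 0
    max_sites: int = 5
    denominator: str = "post_filter"
    weighting: str = "fractional"

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len <= 50):
            raise ValueError("invalid read length bounds")
        if self.denominator not in ("post_filter", "pre_filter"):
            raise ValueError("denominator must be post_filter or pre_filter")
        if self.weighting not in ("fractional", "full"):
            raise ValueError("weighting must be fractional or full")


@dataclass
class ClusterSettings:
    epsilon: float = 100.0
    minpts: int = 10
    k: int = 30
    auto_epsilon: bool = False  # fit epsilon from the k-dist valley of the first sample
    auto_minpts: bool = False  # set minpts = k
    stranded: bool = False
    min_span: int | None = None
    floor_filter: float = 1.0
    min_overlap_frac: float = 0.5
    strict_containment: bool = False
    pseudocount: float = 1.0


@dataclass
class ConservationSettings:
    bin_size: int = 25
    n_resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0
    equal_var: bool = False
    significance_threshold: float = 0.95

    def __post_init__(self):
        if self.bin_size <= 0 or self.n_resamples <= 0:
            raise ValueError("bin_size and n_resamples must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """Inputs, parameters and optional simulation block for run_all.

    When ``simulation`` is present the inputs are generated into the output
    directory first and the path fields may be omitted.
    """

    annotation: str | None = None
    reads: dict[str, str] = field(default_factory=dict)  # sample label -> BED path
    expression: str | None = None
    conservation_track: str | None = None
    chrom_sizes: str | None = None
    centromeres: str | None = None
    filter_fasta: str | None = None
    genome_fasta: str | None = None
    plants: tuple[str, ...] = ("WT", "ap2", "Vandana")
    time_points: tuple[int, ...] = (0, 1, 6)
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    cluster: ClusterSettings = field(default_factory=ClusterSettings)
    conservation: ConservationSettings = field(default_factory=ConservationSettings)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "preprocess" in data and isinstance(data["preprocess"], dict):
            data["preprocess"] = _from_mapping(PreprocessSettings, data["preprocess"], "preprocess")
        if "cluster" in data and isinstance(data["cluster"], dict):
            data["cluster"] = _from_mapping(ClusterSettings, data["cluster"], "cluster")
        if "conservation" in data and isinstance(data["conservation"], dict):
            data["conservation"] = _from_mapping(
                ConservationSettings, data["conservation"], "conservation"
            )
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig.from_mapping(data["simulation"])
        if "plants" in data:
            data["plants"] = tuple(data["plants"])
        if "time_points" in data:
            data["time_points"] = tuple(data["time_points"])
        return _from_mapping(cls, data, "pipeline")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _validate_inputs(config: PipelineConfig, base: Path) -> None:
    required = {"annotation": config.annotation}
    for label, p in config.reads.items():
        required[f"reads[{label}]"] = p
    for name, p in required.items():
        if p is None:
            raise ValueError(f"missing required input: {name}")
        if not (base / p).exists() and not Path(p).exists():
            raise FileNotFoundError(f"input {name} not found: {p}")


def _resolve(base: Path, p: str) -> Path:
    cand = Path(p)
    return cand if cand.is_absolute() or cand.exists() else base / p


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns the run manifest (also written to
    ``manifest.json``). Any stage failure quarantines the partial output
    directory under ``<out_dir>.quarantine`` and re-raises with the stage
    name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.config_hash(),
        "seeds": {
            "simulation": config.simulation.seed if config.simulation else None,
            "conservation": config.conservation.seed,
        },
        "stages": {},
        "outputs": [],
    }
    stage = "validate"
    try:
        if config.simulation is not None:
            stage = "simulate"
            ds = simulate_dataset(config.simulation)
            sim_dir = out / "inputs"
            paths = write_dataset(ds, sim_dir)
            genome_fa = sim_dir / "genome.fasta"
            simulate_genome_fasta(ds.config, ds.layout, genome_fa)
            paths["genome_fasta"] = "genome.fasta"
            config = dataclasses.replace(
                config,
                annotation=str(sim_dir / paths["annotation"]),
                reads={
                    label: str(sim_dir / paths[f"reads_{label}"]) for label in ds.libraries
                },
                expression=str(sim_dir / paths["expression"]),
                conservation_track=str(sim_dir / paths["conservation"]),
                chrom_sizes=str(sim_dir / paths["chrom_sizes"]),
                centromeres=str(sim_dir / paths["centromeres"]),
                filter_fasta=str(sim_dir / paths["filter_fasta"]),
                genome_fasta=str(genome_fa),
                plants=ds.config.plants,
                time_points=ds.config.time_points,
            )
            manifest["stages"]["simulate"] = {
                "n_genes": len(ds.genes),
                "n_planted_clusters": len(ds.truth.clusters),
                "n_reads": {k: int(len(v)) for k, v in sorted(ds.libraries.items())},
            }

        stage = "validate"
        base = out
        _validate_inputs(config, base)

        stage = "annotation"
        genes, layout = read_gff3(_resolve(base, config.annotation))
        if config.chrom_sizes:
            layout2 = GenomeLayout.from_tsv(
                _resolve(base, config.chrom_sizes),
                _resolve(base, config.centromeres) if config.centromeres else None,
            )
            layout = layout2
        manifest["stages"]["annotation"] = {"n_genes": len(genes)}

        stage = "preprocess"
        libraries: dict[str, preprocess.SampleLibrary] = {}
        pp = config.preprocess
        for plant in config.plants:
            for t in config.time_points:
                label = preprocess.sample_label(plant, t)
                if label not in config.reads:
                    raise ValueError(f"no read library configured for sample {label}")
                raw = preprocess.read_bed_reads(_resolve(base, config.reads[label]))
                libraries[label] = preprocess.preprocess_library(
                    raw,
                    plant,
                    t,
                    filter_seqs=(
                        str(_resolve(base, config.filter_fasta)) if config.filter_fasta else None
                    ),
                    min_len=pp.min_len,
                    max_len=pp.max_len,
                    max_mismatch=pp.max_mismatch,
                    max_sites=pp.max_sites,
                    denominator=pp.denominator,
                    weighting=pp.weighting,
                )
        manifest["stages"]["preprocess"] = {
            label: {
                "n_alignments": int(len(lib.reads)),
                "total_processed": round(lib.total_processed, 4),
            }
            for label, lib in sorted(libraries.items())
        }

        stage = "cluster"
        cs = config.cluster
        params = cluster.ClusterParams(epsilon=cs.epsilon, minpts=cs.minpts, k=cs.k)
        if cs.auto_epsilon:
            first = libraries[preprocess.sample_label(config.plants[0], config.time_points[0])]
            starts = first.reads["start"].to_numpy(float)
            profile = cluster.kdist(starts, cs.k)
            sel = cluster.select_epsilon(profile)
            params = cluster.ClusterParams(
                epsilon=sel.epsilon, minpts=(cs.k if cs.auto_minpts else cs.minpts), k=cs.k
            )
            manifest["stages"]["kdist"] = {
                "selected_epsilon": sel.epsilon,
                "low_confidence": sel.low_confidence,
            }
        merged_by_plant: dict[str, list[cluster.SiRNACluster]] = {}
        for plant in config.plants:
            libs = [libraries[preprocess.sample_label(plant, t)] for t in config.time_points]
            merged_by_plant[plant] = cluster.detect_plant_clusters(
                libs,
                params,
                weighting=pp.weighting,
                stranded=cs.stranded,
                min_span=cs.min_span,
            )
        all_samples = sorted(libraries)
        for plant, merged in merged_by_plant.items():
            cluster.write_clusters_bed(merged, out / f"clusters_{plant}.bed")
            cluster.write_cluster_table(merged, all_samples, out / f"clusters_{plant}.tsv")
            manifest["outputs"] += [f"clusters_{plant}.bed", f"clusters_{plant}.tsv"]
        manifest["stages"]["cluster"] = {
            "epsilon": params.epsilon,
            "minpts": params.minpts,
            "n_merged_clusters": {p: len(c) for p, c in sorted(merged_by_plant.items())},
        }

        stage = "associate"
        expression = (
            association.read_expression_tsv(_resolve(base, config.expression))
            if config.expression
            else None
        )
        pairs_by_plant: dict[str, list[association.GeneClusterPair]] = {}
        summaries = {}
        n_intergenic = {}
        for plant, merged in merged_by_plant.items():
            pairs, intergenic = association.assign_targets(
                merged,
                genes,
                min_overlap_frac=cs.min_overlap_frac,
                strict_containment=cs.strict_containment,
            )
            n_intergenic[plant] = len(intergenic)
            cluster.write_clusters_bed(intergenic, out / f"intergenic_{plant}.bed")
            manifest["outputs"].append(f"intergenic_{plant}.bed")
            if expression is not None:
                expr_plant = association.filter_expressed_genes(
                    expression, floor=cs.floor_filter, plant=plant
                )
                pairs = association.attach_expression(
                    pairs, expr_plant, plant, config.time_points, pseudocount=cs.pseudocount
                )
                table, summary = association.correlation_report(pairs)
                table.to_csv(out / f"correlation_{plant}.tsv", sep="\t", index=False)
                manifest["outputs"].append(f"correlation_{plant}.tsv")
                summaries[plant] = summary
            pairs_by_plant[plant] = pairs
            association.write_pairs_tsv(pairs, out / f"pairs_{plant}.tsv")
            with open(out / f"target_genes_{plant}.txt", "w") as fh:
                for p in pairs:
                    fh.write(p.gene_id + "\n")
            manifest["outputs"] += [f"pairs_{plant}.tsv", f"target_genes_{plant}.txt"]
        manifest["stages"]["associate"] = {
            "n_target_genes": {p: len(v) for p, v in sorted(pairs_by_plant.items())},
            "n_intergenic": dict(sorted(n_intergenic.items())),
            "correlation": {
                p: {"r": s["r"], "p": s["p"], "n": s["n"]} for p, s in sorted(summaries.items())
            },
        }

        stage = "enrich"
        gene_by_id = {g.gene_id: g for g in genes}
        index_pairs = []
        for plant, merged in merged_by_plant.items():
            pairs = pairs_by_plant[plant]
            cmap = {c.cluster_id: c for c in merged}
            for p in pairs:
                for cid in p.cluster_ids:
                    index_pairs.append((cmap[cid], gene_by_id[p.gene_id]))
        labels, enr = enrichment.classify_and_enrich(index_pairs, genes)
        enrichment.write_enrichment_tsv(enr, out / "enrichment.tsv")
        manifest["outputs"].append("enrichment.tsv")
        all_merged = [c for merged in merged_by_plant.values() for c in merged]
        if layout.centromeres:
            profile = enrichment.chrom_position_profile(all_merged, layout)
            enrichment.write_position_profile_tsv(profile, out / "chrom_positions.tsv")
            manifest["outputs"].append("chrom_positions.tsv")
        manifest["stages"]["enrich"] = {
            "n_classified": len(labels),
            "odds_ratio": {
                f: (None if v != v or v == float("inf") else round(v, 4))
                for f, v in sorted(enr.odds_ratio.items())
            },
        }

        stage = "conserve"
        if config.conservation_track:
            track = conservation.ConservationTrack.from_bedgraph(
                _resolve(base, config.conservation_track), layout.chrom_sizes
            )
            pooled = cluster.merge_clusters(*merged_by_plant.values(), prefix="pool")
            bins = conservation.bin_feature_regions(genes, bin_size=config.conservation.bin_size)
            conservation.score_bins(bins, track)
            conservation.label_cluster_bins(bins, pooled)
            results = conservation.conservation_tests(
                bins,
                n_resamples=config.conservation.n_resamples,
                alpha=config.conservation.alpha,
                seed=config.conservation.seed,
                equal_var=config.conservation.equal_var,
                significance_threshold=config.conservation.significance_threshold,
            )
            conservation.write_test_results_tsv(results, out / "conservation_tests.tsv")
            manifest["outputs"].append("conservation_tests.tsv")
            intron_bins = [b for b in bins if b.feature == "intron"]
            cdist = conservation.cumulative_score_distribution(intron_bins)
            cdist.to_csv(out / "conservation_cumulative_intron.tsv", sep="\t", index=False)
            manifest["outputs"].append("conservation_cumulative_intron.tsv")
            manifest["stages"]["conserve"] = {
                f: {
                    "n_cluster_bins": r.n_cluster_bins,
                    "median_p": r.median_p,
                    "fraction_significant": r.fraction_significant,
                    "significant": r.significant,
                }
                for f, r in sorted(results.items())
            }

            stage = "export"
            if config.genome_fasta:
                intronic = [
                    c
                    for plant, merged in merged_by_plant.items()
                    for c in merged
                    if labels.get(c.cluster_id) == "intron"
                ]
                conservation.export_cluster_fasta(
                    intronic, _resolve(base, config.genome_fasta), out / "intronic_clusters.fasta"
                )
                manifest["outputs"].append("intronic_clusters.fasta")
                manifest["stages"]["export"] = {"n_intronic_cluster_sequences": len(intronic)}
    except BaseException as exc:
        quarantine = out.parent / (out.name + ".quarantine")
        if quarantine.exists():
            shutil.rmtree(quarantine)
        if out.exists():
            out.rename(quarantine)
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
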