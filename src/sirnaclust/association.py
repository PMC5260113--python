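"""Cluster-to-gene association and expression correlation.

A gene is a *target* when it embodies one or more merged siRNA clusters;
clusters hitting no gene body are intergenic and excluded. For each target
gene the expression of its clusters is summed per sample, giving one
gene/cluster pair per gene. Expression dynamics are compared as log2 fold
changes between consecutive time points (0->1 and 1->6 hours after
treatment) and summarized with a Pearson correlation plus sign-quadrant
counts (gene-down/cluster-up etc.).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .cluster import SiRNACluster
from .intervals import IntervalIndex
from .preprocess import sample_label


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """FPKM table: first column gene_id, remaining columns plant_hat samples."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def filter_expressed_genes(
    table: pd.DataFrame, floor: float = 1.0, plant: str | None = None
) -> pd.DataFrame:
    """Drop genes whose FPKM never exceeds ``floor`` (strictly) at any time
    point. With ``plant`` given, only that plant's columns are evaluated
    (and returned); genes at exactly the floor across the board are removed.
    """
    cols = (
        [c for c in table.columns if c.startswith(f"{plant}_")]
        if plant is not None
        else list(table.columns)
    )
    if plant is not None and not cols:
        raise ValueError(f"no expression columns for plant {plant!r}")
    sub = table[cols]
    return sub.loc[sub.max(axis=1) > floor]


@dataclass
class GeneClusterPair:
    """One target gene with the pooled expression of its clusters."""

    gene_id: str
    cluster_ids: list[str]
    cluster_rpm: dict[str, float] = field(default_factory=dict)  # sample -> summed RPM
    gene_fpkm: dict[str, float] = field(default_factory=dict)
    log2fc_gene: dict[str, float] = field(default_factory=dict)  # interval label -> FC
    log2fc_cluster: dict[str, float] = field(default_factory=dict)


def assign_targets(
    clusters: list[SiRNACluster],
    genes: list[GeneModel],
    min_overlap_frac: float = 0.5,
    strict_containment: bool = False,
) -> tuple[list[GeneClusterPair], list[SiRNACluster]]:
    """Associate merged clusters with the genes that embody them.

    A cluster fully inside a gene body targets that gene. Merging across
    samples can push a hull past a gene edge, so a straddling cluster is
    still assigned when >= ``min_overlap_frac`` of its length lies in the
    body (choosing the gene with the largest overlap; ties by gene_id),
    unless ``strict_containment``. All other clusters are reported as
    intergenic. Returns (pairs sorted by gene_id, intergenic clusters).
    """
    index = IntervalIndex()
    for g in genes:
        index.add(g.body, payload=g)
    by_gene: dict[str, list[SiRNACluster]] = {}
    intergenic: list[SiRNACluster] = []
    for c in clusters:
        hits = index.overlapping_items(c.interval)
        best: tuple[float, str] | None = None
        for body, gene in hits:
            frac = c.interval.overlap_length(body) / c.interval.length()
            if strict_containment:
                ok = frac == 1.0
            else:
                ok = frac >= min_overlap_frac
            if ok and (best is None or (frac, ) > (best[0], ) or (frac == best[0] and gene.gene_id < best[1])):
                best = (frac, gene.gene_id)
        if best is None:
            intergenic.append(c)
        else:
            by_gene.setdefault(best[1], []).append(c)
    pairs = []
    for gene_id in sorted(by_gene):
        cs = by_gene[gene_id]
        rpm: dict[str, float] = {}
        for c in cs:
            for sample, r in c.rpm.items():
                rpm[sample] = rpm.get(sample, 0.0) + r
        pairs.append(
            GeneClusterPair(
                gene_id=gene_id,
                cluster_ids=[c.cluster_id for c in cs],
                cluster_rpm=rpm,
            )
        )
    return pairs, intergenic


def log2_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((b + pseudocount) / (a + pseudocount)); antisymmetric in (a, b)."""
    if a < 0 or b < 0:
        raise ValueError("expression values must be >= 0")
    return math.log2((b + pseudocount) / (a + pseudocount))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-distribution p-value.

    Degenerate input (constant x or y, or fewer than 3 points) is flagged
    with a warning and reported as (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        warnings.warn("pearson correlation needs >= 3 paired values")
        return (float("nan"), float("nan"))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("pearson correlation undefined for zero-variance input")
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def attach_expression(
    pairs: list[GeneClusterPair],
    expression: pd.DataFrame,
    plant: str,
    time_points: tuple[int, ...] = (0, 1, 6),
    pseudocount: float = 1.0,
) -> list[GeneClusterPair]:
    """Fill per-sample gene FPKM and per-interval log2 fold changes.

    Pairs whose gene is absent from the (floor-filtered) expression table
    are dropped. Interval labels are "t0-t1"-style consecutive time spans.
    """
    kept = []
    for pair in pairs:
        if pair.gene_id not in expression.index:
            continue
        for t in time_points:
            s = sample_label(plant, t)
            pair.gene_fpkm[s] = float(expression.at[pair.gene_id, s])
        for t0, t1 in zip(time_points, time_points[1:]):
            label = f"{t0}-{t1}"
            s0, s1 = sample_label(plant, t0), sample_label(plant, t1)
            pair.log2fc_gene[label] = log2_fold_change(
                pair.gene_fpkm[s0], pair.gene_fpkm[s1], pseudocount
            )
            pair.log2fc_cluster[label] = log2_fold_change(
                pair.cluster_rpm.get(s0, 0.0), pair.cluster_rpm.get(s1, 0.0), pseudocount
            )
        kept.append(pair)
    return kept


def correlation_report(pairs: list[GeneClusterPair]) -> tuple[pd.DataFrame, dict]:
    """Scatter table plus summary of gene-vs-cluster fold-change coupling.

    Returns a tidy frame (gene_id, interval, gene_log2fc, cluster_log2fc)
    and a summary with the pooled Pearson r and p, the number of points,
    and sign-quadrant counts; quadrant keys are e.g. "gene_down_cluster_up"
    (zero fold changes count as neither up nor down and land in "on_axis").
    """
    rows = []
    for pair in pairs:
        for label in pair.log2fc_gene:
            rows.append(
                (pair.gene_id, label, pair.log2fc_gene[label], pair.log2fc_cluster[label])
            )
    table = pd.DataFrame(rows, columns=["gene_id", "interval", "gene_log2fc", "cluster_log2fc"])
    if table.empty:
        summary = {
            "r": float("nan"),
            "p": float("nan"),
            "n": 0,
            "quadrants": {},
        }
        return table, summary
    r, p = pearson_correlation(table["gene_log2fc"], table["cluster_log2fc"])
    quad: dict[str, int] = {
        "gene_up_cluster_up": 0,
        "gene_up_cluster_down": 0,
        "gene_down_cluster_up": 0,
        "gene_down_cluster_down": 0,
        "on_axis": 0,
    }
    for g, c in zip(table["gene_log2fc"], table["cluster_log2fc"]):
        if g == 0 or c == 0:
            quad["on_axis"] += 1
        else:
            key = f"gene_{'up' if g > 0 else 'down'}_cluster_{'up' if c > 0 else 'down'}"
            quad[key] += 1
    summary = {"r": r, "p": p, "n": len(table), "quadrants": quad}
    return table, summary


def write_pairs_tsv(pairs: list[GeneClusterPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        samples = sorted({s for p in pairs for s in p.cluster_rpm})
        intervals = sorted({i for p in pairs for i in p.log2fc_gene})
        head = ["gene_id", "cluster_ids"]
        head += [f"cluster_rpm_{s}" for s in samples]
        head += [f"gene_fpkm_{s}" for s in samples]
        head += [f"gene_log2fc_{i}" for i in intervals] + [f"cluster_log2fc_{i}" for i in intervals]
        fh.write("\t".join(head) + "\n")
        for p in pairs:
            row = [p.gene_id, ",".join(p.cluster_ids)]
            row += [f"{p.cluster_rpm.get(s, 0.0):.4f}" for s in samples]
            row += [f"{p.gene_fpkm.get(s, float('nan')):.4f}" for s in samples]
            row += [f"{p.log2fc_gene.get(i, float('nan')):.4f}" for i in intervals]
            row += [f"{p.log2fc_cluster.get(i, float('nan')):.4f}" for i in intervals]
            fh.write("\t".join(row) + "\n")
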