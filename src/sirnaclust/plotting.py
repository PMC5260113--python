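"""SVG plotting helpers for the standard figures of the analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cluster import KDistProfile
from .enrichment import ChromPositionProfile, FeatureEnrichment


def plot_kdist(profile: KDistProfile, path, epsilon: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.values, lw=1)
    if epsilon is not None:
        ax.axhline(epsilon, ls="--", c="k", lw=0.8, label=f"epsilon = {epsilon:g}")
        ax.legend()
    ax.set_xlabel("reads (sorted by k-dist, descending)")
    ax.set_ylabel(f"{profile.k}-dist (bp)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_length_histogram(hist: dict[int, float], path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    lengths = sorted(hist)
    ax.bar(lengths, [hist[l] for l in lengths])
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("RPM")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_enrichment(enrichment: FeatureEnrichment, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    feats = sorted(enrichment.odds_ratio)
    ax.bar(feats, [enrichment.odds_ratio[f] for f in feats])
    ax.axhline(1.0, ls="--", c="k", lw=0.8)
    ax.set_ylabel("length-normalized odds ratio")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cumulative_scores(table: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for col in ("cluster", "noncluster"):
        if col in table:
            ax.plot(table["threshold"], table[col], marker="o", ms=3, label=col)
    ax.set_xlabel("conservation score threshold")
    ax.set_ylabel("cumulative fraction of bins")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_position_profile(profile: ChromPositionProfile, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    ax.bar(centers, profile.density, width=np.diff(profile.bin_edges) * 0.9)
    ax.set_xlabel("relative arm position (0 = centromere, 1 = telomere)")
    ax.set_ylabel("cluster density")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
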