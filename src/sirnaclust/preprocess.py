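"""Small-RNA read filtering and normalization.

Aligned reads are held as a pandas DataFrame with one row per alignment
(columns in :data:`READ_COLUMNS`); :class:`ReadAlignment` is the single
record view. Filtering keeps 18-30 nt reads with no mismatches and at most
five genomic mapping sites; known structural/house-keeping ncRNA reads
(miRNA/rRNA/tRNA/snoRNA) are removed by exact sequence match against a
filter FASTA. Abundances are expressed as reads per million (RPM) of the
library's processed-read total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval

READ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "read_id",
    "score",
    "strand",
    "length",
    "mismatches",
    "n_sites",
    "sequence",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
_VALID_NT = set("ACGTUNacgtun")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped occurrence of a small-RNA read."""

    read_id: str
    interval: GenomicInterval
    length: int
    mismatches: int = 0
    n_sites: int = 1
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.interval.length() != self.length:
            raise ValueError(
                f"alignment span {self.interval.length()} != read length {self.length}"
            )
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def reads_to_frame(reads: Iterable[ReadAlignment]) -> pd.DataFrame:
    rows = [
        (
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.read_id,
            0,
            r.interval.strand,
            r.length,
            r.mismatches,
            r.n_sites,
            r.sequence,
        )
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read_bed_reads(path: str | Path) -> pd.DataFrame:
    """Read alignments from BED6+3(+1): the three extra columns are read
    length, mismatch count and number of mapping sites; an optional tenth
    column carries the read sequence ('.' = absent)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncols = df.shape[1]
    if ncols not in (9, 10):
        raise ValueError(f"{path}: expected 9 or 10 columns, got {ncols}")
    df.columns = READ_COLUMNS[:ncols]
    if ncols == 9:
        df["sequence"] = None
    else:
        df["sequence"] = df["sequence"].where(df["sequence"] != ".", other=None)
    for col in ("start", "end", "length", "mismatches", "n_sites"):
        df[col] = df[col].astype(int)
    return df


def write_bed_reads(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["sequence"] = out["sequence"].fillna(".") if "sequence" in out else "."
    out.to_csv(path, sep="\t", header=False, index=False, columns=READ_COLUMNS)


def alignment_weights(df: pd.DataFrame, weighting: str = "fractional") -> np.ndarray:
    """Per-alignment count contribution: 1/n_sites (fractional) or 1 (full)."""
    if weighting == "fractional":
        return 1.0 / df["n_sites"].to_numpy(float)
    if weighting == "full":
        return np.ones(len(df))
    raise ValueError(f"unknown weighting {weighting!r}")


def filter_alignments(
    df: pd.DataFrame,
    min_len: int = 18,
    max_len: int = 30,
    max_mismatch: int = 0,
    max_sites: int = 5,
) -> pd.DataFrame:
    """Retain alignments with min_len <= length <= max_len, at most
    ``max_mismatch`` mismatches and at most ``max_sites`` mapping sites.
    Row order is preserved."""
    keep = (
        (df["length"] >= min_len)
        & (df["length"] <= max_len)
        & (df["mismatches"] <= max_mismatch)
        & (df["n_sites"] <= max_sites)
    )
    return df.loc[keep]


def load_filter_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")}


def filter_ncrna(df: pd.DataFrame, filter_seqs: Mapping[str, str] | str | Path | None) -> pd.DataFrame:
    """Drop reads whose sequence matches a filter-set sequence exactly.

    A read is removed iff its sequence is an exact substring of any filter
    sequence on either strand (reverse-complement aware); removal is by
    read_id, so every alignment of a matched read drops. Without sequences
    (or without a filter set) this is a pass-through with a warning.
    """
    if filter_seqs is None:
        return df
    if isinstance(filter_seqs, (str, Path)):
        filter_seqs = load_filter_fasta(filter_seqs)
    has_seq = df["sequence"].notna()
    if not has_seq.any():
        warnings.warn("filter set given but reads carry no sequences; ncRNA filter skipped")
        return df
    haystack = "|".join(s.upper().replace("U", "T") for s in filter_seqs.values())
    bad_ids: set[str] = set()
    seq_groups = df.loc[has_seq].groupby("sequence")["read_id"]
    for seq, ids in seq_groups:
        s = str(seq).upper().replace("U", "T")
        if not set(s) <= _VALID_NT:
            raise ValueError(f"invalid nucleotide characters in read sequence {seq!r}")
        if s in haystack or reverse_complement(s) in haystack:
            bad_ids.update(ids)
    if not bad_ids:
        return df
    return df.loc[~df["read_id"].isin(bad_ids)]


def normalize_rpm(count: float, total_processed: float) -> float:
    """Reads-per-million: count * 1e6 / total_processed."""
    if total_processed <= 0:
        raise ValueError("total_processed must be > 0")
    return count * 1e6 / total_processed


@dataclass
class SampleLibrary:
    """A preprocessed per-sample read library.

    ``total_processed`` is the weighted number of processed reads used as
    the RPM denominator (post-filter by default).
    """

    plant: str
    time_hat: int
    reads: pd.DataFrame
    total_processed: float

    @property
    def label(self) -> str:
        return f"{self.plant}_{self.time_hat}"


def sample_label(plant: str, time_hat: int) -> str:
    return f"{plant}_{time_hat}"


def preprocess_library(
    raw: pd.DataFrame,
    plant: str,
    time_hat: int,
    filter_seqs: Mapping[str, str] | str | Path | None = None,
    min_len: int = 18,
    max_len: int = 30,
    max_mismatch: int = 0,
    max_sites: int = 5,
    denominator: str = "post_filter",
    weighting: str = "fractional",
) -> SampleLibrary:
    """Apply ncRNA + alignment filters and fix the RPM denominator.

    ``denominator`` selects whether the weighted read total is taken before
    ("pre_filter") or after ("post_filter", default) filtering.
    """
    if denominator not in ("post_filter", "pre_filter"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    pre_total = float(alignment_weights(raw, weighting).sum())
    df = filter_ncrna(raw, filter_seqs)
    df = filter_alignments(df, min_len, max_len, max_mismatch, max_sites)
    df = df.reset_index(drop=True)
    total = pre_total if denominator == "pre_filter" else float(alignment_weights(df, weighting).sum())
    if total <= 0:
        total = 1.0  # empty library: RPM values are all zero anyway
    return SampleLibrary(plant=plant, time_hat=time_hat, reads=df, total_processed=total)


def length_histogram(
    library: SampleLibrary,
    min_len: int = 18,
    max_len: int = 30,
    weighting: str = "fractional",
) -> dict[int, float]:
    """Per-length RPM over the retained reads (the length profile of the
    library; in drought libraries two modes at 21 and 24 nt are expected)."""
    w = alignment_weights(library.reads, weighting)
    hist = {length: 0.0 for length in range(min_len, max_len + 1)}
    if len(library.reads):
        sums = pd.Series(w).groupby(library.reads["length"].to_numpy()).sum()
        for length, total in sums.items():
            if min_len <= length <= max_len:
                hist[int(length)] = normalize_rpm(float(total), library.total_processed)
    return hist
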