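"""Gene annotation model: GFF3 parsing and per-gene sub-feature derivation.

A :class:`GeneModel` carries the gene body span plus derived sub-features of
its representative transcript (the longest-spanning mRNA): introns (gaps
between consecutive exons), CDS, and UTRs inferred from the CDS extent in
transcript orientation. GFF3 1-based inclusive coordinates are converted to
the package's 0-based half-open convention on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import GenomeLayout, GenomicInterval

FEATURE_LABELS = ("five_prime_utr", "cds", "intron", "three_prime_utr")

#: GFF3 type spellings accepted for UTR records on write/read.
_GFF3_TYPE = {
    "five_prime_utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "cds": "CDS",
    "intron": "intron",
}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GeneModel:
    """A gene body with sub-features of its representative transcript."""

    gene_id: str
    body: GenomicInterval
    transcript_id: str | None = None
    exons: tuple[GenomicInterval, ...] = ()
    features: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, ivs in self.features.items():
            if label not in FEATURE_LABELS:
                raise AnnotationError(f"unknown feature label {label!r}")
            for iv in ivs:
                if not self.body.contains(iv):
                    raise AnnotationError(
                        f"feature {label} {iv} of {self.gene_id} outside gene body {self.body}"
                    )
            ordered = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ordered, ordered[1:]):
                if a.end > b.start:
                    raise AnnotationError(
                        f"{label} intervals overlap in {self.gene_id}: {a} vs {b}"
                    )

    @property
    def strand(self) -> str:
        return self.body.strand

    def feature_intervals(self, label: str) -> tuple[GenomicInterval, ...]:
        return self.features.get(label, ())

    def introns(self) -> tuple[GenomicInterval, ...]:
        return self.feature_intervals("intron")


def _introns_from_exons(exons: Sequence[GenomicInterval], strand: str) -> tuple[GenomicInterval, ...]:
    exs = sorted(exons, key=lambda iv: iv.start)
    out = []
    for a, b in zip(exs, exs[1:]):
        if a.end > b.start:
            raise AnnotationError(f"exons overlap: {a} vs {b}")
        if b.start > a.end:
            out.append(GenomicInterval(a.chrom, a.end, b.start, strand))
    return tuple(out)


def derive_utrs(
    exons: Sequence[GenomicInterval],
    cds: Sequence[GenomicInterval],
    strand: str,
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    """Split exonic sequence outside the CDS extent into 5'/3' UTR pieces.

    Exonic bases upstream of the first coding base (in transcript
    orientation) form the 5' UTR; bases downstream of the last coding base
    form the 3' UTR. Returns ``(five_prime_utr, three_prime_utr)`` interval
    tuples. Raises :class:`AnnotationError` if the CDS is not contained in
    the exons.
    """
    if not cds:
        return (), ()
    exs = sorted(exons, key=lambda iv: iv.start)
    for c in cds:
        if not any(e.contains(c) for e in exs):
            raise AnnotationError(f"CDS segment {c} not contained in any exon")
    cds_lo = min(c.start for c in cds)
    cds_hi = max(c.end for c in cds)
    left, right = [], []
    for e in exs:
        if e.start < cds_lo:
            left.append(GenomicInterval(e.chrom, e.start, min(e.end, cds_lo), strand))
        if e.end > cds_hi:
            right.append(GenomicInterval(e.chrom, max(e.start, cds_hi), e.end, strand))
    if strand == "-":
        return tuple(right), tuple(left)
    return tuple(left), tuple(right)


def build_gene_model(
    gene_id: str,
    body: GenomicInterval,
    exons: Sequence[GenomicInterval],
    cds: Sequence[GenomicInterval] = (),
    transcript_id: str | None = None,
) -> GeneModel:
    """Assemble a GeneModel from exon/CDS intervals of one transcript."""
    strand = body.strand
    for e in exons:
        if not body.contains(e):
            raise AnnotationError(f"exon {e} outside gene span {body} of {gene_id}")
    features: dict[str, tuple[GenomicInterval, ...]] = {}
    introns = _introns_from_exons(exons, strand)
    if introns:
        features["intron"] = introns
    if cds:
        features["cds"] = tuple(sorted(cds, key=lambda iv: iv.start))
        utr5, utr3 = derive_utrs(exons, cds, strand)
        if utr5:
            features["five_prime_utr"] = utr5
        if utr3:
            features["three_prime_utr"] = utr3
    return GeneModel(
        gene_id=gene_id,
        body=body,
        transcript_id=transcript_id,
        exons=tuple(sorted(exons, key=lambda iv: iv.start)),
        features=features,
    )


def _validate_gff3_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: invalid coordinates {start}..{end}"
                )


def read_gff3(path: str | Path) -> tuple[list[GeneModel], GenomeLayout]:
    """Parse a GFF3 file into GeneModels plus a genome layout.

    One GeneModel per ``gene`` record; with multiple mRNAs the longest
    spanning transcript is the representative (ties by lexicographically
    smallest transcript id). Chromosome sizes come from ``##sequence-region``
    pragmas when present, otherwise from the maximum annotated coordinate;
    centromeres are not part of GFF3 and stay empty.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        body = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand if g.strand in "+-" else ".")
        mrnas = list(db.children(g, featuretype=("mRNA", "transcript")))
        if mrnas:
            rep = min(mrnas, key=lambda m: (-(m.end - m.start + 1), m.id))
            exon_feats = list(db.children(rep, featuretype="exon"))
            cds_feats = list(db.children(rep, featuretype="CDS"))
            tx_id = rep.id
        else:
            exon_feats = list(db.children(g, featuretype="exon"))
            cds_feats = list(db.children(g, featuretype="CDS"))
            tx_id = None
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, body.strand) for e in exon_feats
        ]
        cds = [GenomicInterval(c.seqid, c.start - 1, c.end, body.strand) for c in cds_feats]
        if not exons:
            exons = [body]
        for e in exons:
            if not body.contains(e):
                raise AnnotationError(
                    f"exon {e} outside gene span of {g.id} ({body})"
                )
        genes.append(build_gene_model(g.id, body, exons, cds, transcript_id=tx_id))

    if not sizes:
        for gm in genes:
            sizes[gm.body.chrom] = max(sizes.get(gm.body.chrom, 0), gm.body.end)
    layout = GenomeLayout(chrom_sizes=sizes)
    return genes, layout


def write_gff3(
    genes: Iterable[GeneModel],
    path: str | Path,
    layout: GenomeLayout | None = None,
) -> None:
    """Serialize GeneModels back to GFF3 (gene/mRNA/exon/CDS/UTR records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if layout is not None:
            for chrom in sorted(layout.chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {layout.chrom_sizes[chrom]}\n")

        def rec(chrom, ftype, iv, strand, attrs):
            fh.write(
                f"{chrom}\tsirnaclust\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}\n"
            )

        for gm in sorted(genes, key=lambda g: (g.body.chrom, g.body.start)):
            strand = gm.strand if gm.strand in "+-" else "."
            rec(gm.body.chrom, "gene", gm.body, strand, f"ID={gm.gene_id}")
            tx = gm.transcript_id or f"{gm.gene_id}.t1"
            rec(gm.body.chrom, "mRNA", gm.body, strand, f"ID={tx};Parent={gm.gene_id}")
            for i, e in enumerate(gm.exons, 1):
                rec(gm.body.chrom, "exon", e, strand, f"ID={tx}.exon{i};Parent={tx}")
            for label in ("cds", "five_prime_utr", "three_prime_utr"):
                for i, iv in enumerate(gm.feature_intervals(label), 1):
                    rec(
                        gm.body.chrom,
                        _GFF3_TYPE[label],
                        iv,
                        strand,
                        f"ID={tx}.{label}{i};Parent={tx}",
                    )


def total_feature_lengths(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Summed bp per feature label over all genes' representative transcripts."""
    totals: dict[str, int] = {}
    for gm in genes:
        for label, ivs in gm.features.items():
            totals[label] = totals.get(label, 0) + sum(iv.length() for iv in ivs)
    return totals
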