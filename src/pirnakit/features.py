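"""Annotation feature containers and GFF3/BED input/output.

Holds the interval sets the annotation hierarchy is built from: piRNA
clusters, repeats, and gene models carrying exon / CDS / UTR sub-features.
Introns are implied (gene body minus exons) rather than stored explicitly.
All coordinates are 0-based half-open internally; GFF3 I/O converts to and
from its 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .core import GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure and, when coding, CDS/UTR sub-features."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    coding: bool
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for e in self.exons:
            if not self.interval.contains(e):
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gene body minus exons, computed on demand."""
        out = []
        exons = sorted(self.exons, key=lambda e: e.start)
        cursor = self.interval.start
        for e in exons:
            if e.start > cursor:
                out.append(
                    GenomicInterval(
                        self.interval.chrom, cursor, e.start, self.interval.strand
                    )
                )
            cursor = max(cursor, e.end)
        if cursor < self.interval.end:
            out.append(
                GenomicInterval(
                    self.interval.chrom, cursor, self.interval.end,
                    self.interval.strand,
                )
            )
        return tuple(out)


@dataclass
class AnnotationSet:
    """The complete annotation used for hierarchical read classification."""

    clusters: list[GenomicInterval] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.coding]

    @property
    def noncoding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if not g.coding]


# ---------------------------------------------------------------------------
# BED / GFF3 output


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              name_prefix: str = "feature") -> None:
    """Write intervals as BED6."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\t0\t{strand}\n"
            )


def _gff_line(chrom: str, ftype: str, start: int, end: int, strand: str,
              attrs: str) -> str:
    s = strand if strand != "." else "."
    return f"{chrom}\tpirnakit\t{ftype}\t{start + 1}\t{end}\t.\t{s}\t.\t{attrs}\n"


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write the full annotation as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(annotation.clusters):
            fh.write(_gff_line(iv.chrom, "piRNA_cluster", iv.start, iv.end,
                               iv.strand, f"ID=cluster_{i}"))
        for i, iv in enumerate(annotation.repeats):
            fh.write(_gff_line(iv.chrom, "repeat_region", iv.start, iv.end,
                               iv.strand, f"ID=repeat_{i}"))
        for g in annotation.genes:
            biotype = "protein_coding" if g.coding else "non_coding"
            fh.write(_gff_line(g.interval.chrom, "gene", g.interval.start,
                               g.interval.end, g.interval.strand,
                               f"ID={g.gene_id};biotype={biotype}"))
            for j, e in enumerate(g.exons):
                fh.write(_gff_line(e.chrom, "exon", e.start, e.end, e.strand,
                                   f"ID={g.gene_id}.exon{j};Parent={g.gene_id}"))
            for j, c in enumerate(g.cds):
                fh.write(_gff_line(c.chrom, "CDS", c.start, c.end, c.strand,
                                   f"ID={g.gene_id}.cds{j};Parent={g.gene_id}"))
            for j, u in enumerate(g.utr5):
                fh.write(_gff_line(u.chrom, "five_prime_UTR", u.start, u.end,
                                   u.strand,
                                   f"ID={g.gene_id}.utr5.{j};Parent={g.gene_id}"))
            for j, u in enumerate(g.utr3):
                fh.write(_gff_line(u.chrom, "three_prime_UTR", u.start, u.end,
                                   u.strand,
                                   f"ID={g.gene_id}.utr3.{j};Parent={g.gene_id}"))


# ---------------------------------------------------------------------------
# BED / GFF3 input


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals (strand '.' when absent)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read an annotation written by :func:`write_gff3` (or any GFF3 using
    the same feature types and Parent links)."""
    import pandas as pd

    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "frame", "attrs"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#",
                     dtype={"chrom": str})
    ann = AnnotationSet()
    gene_rows: dict[str, dict] = {}
    children: dict[str, dict[str, list[GenomicInterval]]] = {}
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start) - 1, int(row.end),
                             row.strand if row.strand in ("+", "-") else ".")
        attrs = _parse_attrs(row.attrs)
        ftype = row.type
        if ftype == "piRNA_cluster":
            ann.clusters.append(iv)
        elif ftype in ("repeat_region", "repeat"):
            ann.repeats.append(iv)
        elif ftype == "gene":
            gene_rows[attrs.get("ID", f"gene{len(gene_rows)}")] = {
                "interval": iv,
                "coding": attrs.get("biotype", "protein_coding") == "protein_coding",
            }
        elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            parent = attrs.get("Parent")
            if parent is None:
                continue
            slot = {"exon": "exons", "CDS": "cds", "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3"}[ftype]
            children.setdefault(parent, {}).setdefault(slot, []).append(iv)
    for gid, info in gene_rows.items():
        kid = children.get(gid, {})
        ann.genes.append(
            GeneModel(
                gene_id=gid,
                interval=info["interval"],
                exons=tuple(kid.get("exons", [])),
                coding=info["coding"],
                cds=tuple(kid.get("cds", [])),
                utr5=tuple(kid.get("utr5", [])),
                utr3=tuple(kid.get("utr3", [])),
            )
        )
    return ann
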