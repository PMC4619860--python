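"""piRNA calling and exclusive hierarchical genomic annotation.

A read is called a piRNA on length alone (23-32 nt by default); primary
status means U at read position 1 and secondary status means A at read
position 10, both evaluated on the read-space sequence (the RNA, not the
reference strand), 1-based from the 5' end. A read may be both.

Annotation is exclusive with the priority
piRNA_cluster > repeat > exon_coding > exon_noncoding > intron, and
intergenic when nothing overlaps by at least 1 bp. Reads landing in
clusters are candidate piRNAs and are re-classified against the remaining
sets for a secondary annotation; coding-exon reads get a 5'UTR/CDS/3'UTR
subtype. Antisense means the read's strand is opposite to the winning
stranded feature (largest overlap decides ties; sense wins exact ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import AlignedRead, FilterPolicy, GenomicInterval, SampleSet
from .features import AnnotationSet

logger = logging.getLogger(__name__)

#: exclusive annotation priority, highest first; intergenic is the fallback
PRIORITY = ("piRNA_cluster", "repeat", "exon_coding", "exon_noncoding", "intron")

MRNA_SUBTYPES = ("5'UTR", "CDS", "3'UTR")


@dataclass(frozen=True)
class PiRNACall:
    """Length/1U/10A classification plus the exclusive annotation."""

    is_pirna: bool
    is_primary: bool
    is_secondary: bool
    category: str = "intergenic"
    antisense: bool = False
    mrna_subtype: str = "none"
    secondary_category: str = "none"  # within-cluster re-classification


def classify_pirna(read: AlignedRead, policy: FilterPolicy = FilterPolicy()
                   ) -> PiRNACall:
    """Call piRNA status from the read sequence alone.

    Pure function of (seq, policy): independent of genomic position and
    strand. 1U/10A flags are only meaningful (and only set) when the length
    criterion holds; both may be set on one read.
    """
    n = len(read.seq)
    is_pirna = policy.is_pirna_length(n)
    if not is_pirna:
        return PiRNACall(False, False, False)
    is_primary = read.seq[0] == "T"
    is_secondary = n >= 10 and read.seq[9] == "A"
    return PiRNACall(True, is_primary, is_secondary)


class AnnotationIndex:
    """Interval trees over every annotation layer, keyed for priority lookup.

    Each tree maps genomic spans to (feature_strand, payload) where payload
    is the mRNA subtype for coding-exon sub-features.
    """

    def __init__(self, annotation: AnnotationSet):
        self.annotation = annotation
        self._trees: dict[str, dict[str, IntervalTree]] = {
            layer: {} for layer in PRIORITY
        }
        for iv in annotation.clusters:
            self._add("piRNA_cluster", iv, "none")
        for iv in annotation.repeats:
            self._add("repeat", iv, "none")
        for g in annotation.genes:
            strand = g.interval.strand
            if g.coding:
                for sub, name in ((g.utr5, "5'UTR"), (g.cds, "CDS"),
                                  (g.utr3, "3'UTR")):
                    for iv in sub:
                        self._add("exon_coding", iv, name)
                # exons not covered by CDS/UTR splits (defensive: a gene
                # model may carry bare exons only)
                if not (g.cds or g.utr5 or g.utr3):
                    for iv in g.exons:
                        self._add("exon_coding", iv, "none")
            else:
                for iv in g.exons:
                    self._add("exon_noncoding", iv, "none")
            for iv in g.introns:
                self._add("intron", iv, "none")

    def _add(self, layer: str, iv: GenomicInterval, payload: str) -> None:
        tree = self._trees[layer].setdefault(iv.chrom, IntervalTree())
        tree.addi(iv.start, iv.end, (iv.strand, payload))

    def hits(self, layer: str, read: AlignedRead
             ) -> list[tuple[int, int, str, str]]:
        """(start, end, feature_strand, payload) of >=1 bp overlaps."""
        tree = self._trees[layer].get(read.interval.chrom)
        if tree is None:
            return []
        return sorted(
            (h.begin, h.end, h.data[0], h.data[1])
            for h in tree.overlap(read.interval.start, read.interval.end)
        )


def _antisense_and_payload(read: AlignedRead,
                           hits: Sequence[tuple[int, int, str, str]]
                           ) -> tuple[bool, str]:
    """Resolve antisense and subtype from the largest-overlap feature.

    Exact overlap ties resolve to sense (conservative); an unstranded
    feature is never antisense.
    """
    best_olap = -1
    antisense = False
    payload = "none"
    warned = False
    for start, end, strand, pl in hits:
        olap = min(end, read.interval.end) - max(start, read.interval.start)
        anti = strand in ("+", "-") and strand != read.strand
        if strand not in ("+", "-") and not warned:
            warned = True
        if olap > best_olap or (olap == best_olap and not anti and antisense):
            best_olap = olap
            antisense = anti
            payload = pl
    return antisense, payload


def annotate_read(read: AlignedRead, index: AnnotationIndex) -> PiRNACall:
    """Exclusive category by priority order, plus antisense and subtype.

    Not a full piRNA call: use :func:`classify_and_annotate` to combine with
    the sequence criteria.
    """
    category = "intergenic"
    antisense = False
    subtype = "none"
    secondary = "none"
    winning_hits: Sequence = ()
    for layer in PRIORITY:
        hits = index.hits(layer, read)
        if hits:
            category = layer
            winning_hits = hits
            break
    if winning_hits:
        antisense, subtype = _antisense_and_payload(read, winning_hits)
        if category != "exon_coding":
            subtype = "none"
    if category == "piRNA_cluster":
        # candidate piRNAs: re-classify against the remaining sets
        secondary = "intergenic"
        for layer in PRIORITY[1:]:
            hits = index.hits(layer, read)
            if hits:
                secondary = layer
                anti2, sub2 = _antisense_and_payload(read, hits)
                if layer == "exon_coding":
                    subtype = sub2
                break
    return PiRNACall(
        is_pirna=False, is_primary=False, is_secondary=False,
        category=category, antisense=antisense, mrna_subtype=subtype,
        secondary_category=secondary,
    )


def classify_and_annotate(
    sample: SampleSet,
    index: AnnotationIndex,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Per-read table of piRNA calls and exclusive annotations."""
    sample.require_nonempty("classification")
    rows = []
    for read in sample.reads:
        call = classify_pirna(read, policy)
        ann = annotate_read(read, index)
        rows.append(dict(
            read_id=read.read_id,
            length=len(read.seq),
            is_pirna=call.is_pirna,
            is_primary=call.is_primary,
            is_secondary=call.is_secondary,
            category=ann.category,
            antisense=ann.antisense,
            mrna_subtype=ann.mrna_subtype,
            secondary_category=ann.secondary_category,
        ))
    return pd.DataFrame.from_records(rows)


def partition_by_intervals(
    sample: SampleSet,
    intervals: Iterable[GenomicInterval],
    label: str,
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[SampleSet, float]:
    """Subset of size-selected reads overlapping an interval set by >=1 bp.

    Used to partition libraries by externally defined coordinates (for
    example MILI- or MIWI-bound HITS-CLIP intervals). Returns the subset and
    its percentage of the sample's size-selected (piRNA-length) reads.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    selected = sample.pirna_reads(policy)
    subset = [
        r for r in selected
        if (t := trees.get(r.interval.chrom)) is not None
        and t.overlaps(r.interval.start, r.interval.end)
    ]
    pct = 100.0 * len(subset) / len(selected) if selected else 0.0
    return sample.subset(subset, suffix=label), pct


def summarize_categories(
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category counts and percentages over all retained reads.

    Also reports the percent of reads within clusters and the percent
    meeting the piRNA length criterion, as extra rows. Percentages over
    categories sum to 100 exactly.
    """
    if calls.empty:
        raise ValueError("no reads to summarize")
    n = len(calls)
    counts = calls["category"].value_counts()
    rows = []
    all_cats = list(PRIORITY) + ["intergenic"]
    for cat in all_cats:
        c = int(counts.get(cat, 0))
        rows.append(dict(metric="category", name=cat, count=c,
                         percent=100.0 * c / n))
    rows.append(dict(
        metric="summary", name="in_clusters",
        count=int(counts.get("piRNA_cluster", 0)),
        percent=100.0 * counts.get("piRNA_cluster", 0) / n,
    ))
    n_crit = int(calls["is_pirna"].sum())
    rows.append(dict(metric="summary", name="meets_pirna_criteria",
                     count=n_crit, percent=100.0 * n_crit / n))
    return pd.DataFrame.from_records(rows)
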