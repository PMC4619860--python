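"""Binned global and differential piRNA expression.

Filtered alignments are tallied into fixed-width genomic bins (10 Mbp by
default) stratified by read length (20-35 nt by default), with summed
counts for a long pool (28-32 nt) and a short pool (23-27 nt) and a count
of distinct 5' ends per bin. Because piRNAs truncate mainly from the 3'
end, unique 5' ends proxy the number of distinct piRNA species ("genus");
optional denesting counts a 5' end only when its alignment is not fully
encompassed by another alignment, collapsing truncation ladders onto their
longest form.

Differential expression subtracts one sample's tallies from another's
bin-by-bin and length-by-length; unique-5'-end counts are kept separately
per sample rather than differenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import AlignedRead, FilterPolicy, GenomicInterval, SampleSet
from .annotate import classify_pirna


@dataclass(frozen=True)
class BinningSpec:
    """Binning and length-stratification parameters."""

    bin_size: int = 10_000_000
    length_min: int = 20
    length_max: int = 35
    long_pool: tuple[int, int] = (28, 32)
    short_pool: tuple[int, int] = (23, 27)
    denest: bool = False
    per_bp: bool = True

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        lo_l, hi_l = self.long_pool
        lo_s, hi_s = self.short_pool
        if not (lo_s <= hi_s and lo_l <= hi_l):
            raise ValueError("pool bounds inverted")
        if max(lo_s, lo_l) <= min(hi_s, hi_l):
            raise ValueError("long and short pools must be disjoint")
        for b in (lo_l, hi_l, lo_s, hi_s):
            if not (self.length_min <= b <= self.length_max):
                raise ValueError("pool bounds outside stratification range")

    def in_long(self, n: int) -> bool:
        return self.long_pool[0] <= n <= self.long_pool[1]

    def in_short(self, n: int) -> bool:
        return self.short_pool[0] <= n <= self.short_pool[1]


def denest(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Reduce intervals (one chromosome + strand) to the non-nested subset.

    Duplicates are removed first; an interval survives when no *distinct*
    interval contains it (B contains A iff B.start <= A.start and
    A.end <= B.end and B != A). The result is antichain-maximal: no output
    interval contains another, and every input interval is contained in
    some output interval.
    """
    unique = sorted(set(intervals), key=lambda iv: (iv[0], -iv[1]))
    out: list[tuple[int, int]] = []
    max_end = -1
    for start, end in unique:
        # any earlier interval in this order has start <= ours; it contains
        # us iff its end >= ours (equality cannot be the same interval)
        if end > max_end:
            out.append((start, end))
            max_end = end
    return out


@dataclass
class BinMatrix:
    """Per-(chrom, bin, length) alignment tallies for one sample."""

    sample_id: str
    spec: BinningSpec
    chrom_sizes: dict[str, int]
    counts: dict[tuple[str, int, int], int] = field(default_factory=dict)
    unique5: dict[tuple[str, int], int] = field(default_factory=dict)
    n_in_range: int = 0
    n_out_of_range: int = 0

    def _bin_width(self, chrom: str, bin_idx: int) -> int:
        size = self.chrom_sizes.get(chrom)
        if size is None:
            return self.spec.bin_size
        lo = bin_idx * self.spec.bin_size
        return min(self.spec.bin_size, size - lo)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pool_sums(self) -> dict[tuple[str, int], tuple[int, int]]:
        """Per-bin (long_pool_sum, short_pool_sum)."""
        out: dict[tuple[str, int], list[int]] = {}
        for (chrom, b, L), c in self.counts.items():
            cell = out.setdefault((chrom, b), [0, 0])
            if self.spec.in_long(L):
                cell[0] += c
            elif self.spec.in_short(L):
                cell[1] += c
        return {k: (v[0], v[1]) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chrom, bin_start, bin_end, length, count, count_per_bp)."""
        rows = []
        for (chrom, b, L), c in sorted(self.counts.items()):
            lo = b * self.spec.bin_size
            width = self._bin_width(chrom, b)
            rows.append(dict(
                chrom=chrom, bin_start=lo, bin_end=lo + width, length=L,
                count=c, count_per_bp=c / width,
            ))
        return pd.DataFrame.from_records(
            rows, columns=["chrom", "bin_start", "bin_end", "length",
                           "count", "count_per_bp"]
        )

    def bin_summary(self) -> pd.DataFrame:
        """Per-bin long/short pool sums and unique-5'-end counts."""
        pools = self.pool_sums()
        keys = sorted(set(pools) | set(self.unique5))
        rows = []
        for chrom, b in keys:
            lo = b * self.spec.bin_size
            long_sum, short_sum = pools.get((chrom, b), (0, 0))
            rows.append(dict(
                chrom=chrom, bin_start=lo,
                bin_end=lo + self._bin_width(chrom, b),
                long_pool=long_sum, short_pool=short_sum,
                unique_5p_ends=self.unique5.get((chrom, b), 0),
            ))
        return pd.DataFrame.from_records(
            rows, columns=["chrom", "bin_start", "bin_end", "long_pool",
                           "short_pool", "unique_5p_ends"]
        )


def _feature_trees(features: Sequence[GenomicInterval]
                   ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def bin_expression(
    sample: SampleSet,
    spec: BinningSpec = BinningSpec(),
    chrom_sizes: Optional[Mapping[str, int]] = None,
    pirna_class: Optional[str] = None,
    feature_filter: Optional[Sequence[GenomicInterval]] = None,
    policy: FilterPolicy = FilterPolicy(),
) -> BinMatrix:
    """Tally alignments into genomic bins stratified by read length.

    ``pirna_class`` of 'primary' / 'secondary' restricts to 1U / 10A piRNA
    reads; ``feature_filter`` keeps only alignments overlapping the given
    intervals by >= 1 bp. Bin index is floor(alignment start / bin_size);
    per-bp values divide by the bin's actual width (the final partial bin by
    its true width). Unique 5' ends are keyed by (chrom, strand, position)
    and, with ``spec.denest``, counted only for alignments not fully
    encompassed by another alignment on the same chromosome and strand.
    Alignments outside [length_min, length_max] are tallied separately,
    never dropped silently.
    """
    sample.require_nonempty("binning")
    if pirna_class not in (None, "primary", "secondary"):
        raise ValueError(f"unknown pirna_class {pirna_class!r}")
    trees = _feature_trees(feature_filter) if feature_filter is not None else None
    matrix = BinMatrix(
        sample_id=sample.sample_id, spec=spec,
        chrom_sizes=dict(chrom_sizes or {}),
    )
    kept: list[AlignedRead] = []
    for read in sample.reads:
        if pirna_class is not None:
            call = classify_pirna(read, policy)
            if pirna_class == "primary" and not (call.is_pirna and call.is_primary):
                continue
            if pirna_class == "secondary" and not (call.is_pirna and call.is_secondary):
                continue
        if trees is not None:
            t = trees.get(read.interval.chrom)
            if t is None or not t.overlaps(read.interval.start, read.interval.end):
                continue
        L = len(read.seq)
        if not (spec.length_min <= L <= spec.length_max):
            matrix.n_out_of_range += 1
            continue
        kept.append(read)
        b = read.interval.start // spec.bin_size
        key = (read.interval.chrom, b, L)
        matrix.counts[key] = matrix.counts.get(key, 0) + 1
        matrix.n_in_range += 1
    # unique 5' ends, optionally denested, per (chrom, strand)
    by_cs: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in kept:
        by_cs.setdefault((read.interval.chrom, read.strand), []).append(read)
    ends: set[tuple[str, str, int]] = set()
    for (chrom, strand), reads in by_cs.items():
        if spec.denest:
            ivs = denest((r.interval.start, r.interval.end) for r in reads)
            for start, end in ivs:
                pos = start if strand == "+" else end - 1
                ends.add((chrom, strand, pos))
        else:
            for r in reads:
                ends.add((chrom, strand, r.five_prime))
    for chrom, strand, pos in ends:
        key = (chrom, pos // spec.bin_size)
        matrix.unique5[key] = matrix.unique5.get(key, 0) + 1
    return matrix


@dataclass
class DiffBinMatrix:
    """Bin/length-wise count differences (sample B minus sample A)."""

    sample_a: str
    sample_b: str
    spec: BinningSpec
    chrom_sizes: dict[str, int]
    diff: dict[tuple[str, int, int], int]
    unique5_a: dict[tuple[str, int], int]
    unique5_b: dict[tuple[str, int], int]

    def pool_diffs(self) -> dict[tuple[str, int], tuple[int, int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for (chrom, b, L), d in self.diff.items():
            cell = out.setdefault((chrom, b), [0, 0])
            if self.spec.in_long(L):
                cell[0] += d
            elif self.spec.in_short(L):
                cell[1] += d
        return {k: (v[0], v[1]) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, b, L), d in sorted(self.diff.items()):
            lo = b * self.spec.bin_size
            size = self.chrom_sizes.get(chrom)
            width = self.spec.bin_size if size is None else \
                min(self.spec.bin_size, size - lo)
            rows.append(dict(chrom=chrom, bin_start=lo, bin_end=lo + width,
                             length=L, count_diff=d, count_diff_per_bp=d / width))
        return pd.DataFrame.from_records(
            rows, columns=["chrom", "bin_start", "bin_end", "length",
                           "count_diff", "count_diff_per_bp"]
        )


def differential_bins(a: BinMatrix, b: BinMatrix) -> DiffBinMatrix:
    """Elementwise difference (b - a) of two matrices built with one spec.

    Unique-5'-end counts are carried through per sample, not differenced.
    A spec mismatch is an error — no silent rebinning.
    """
    if a.spec != b.spec:
        raise ValueError("BinningSpec mismatch between the two matrices")
    keys = set(a.counts) | set(b.counts)
    diff = {k: b.counts.get(k, 0) - a.counts.get(k, 0) for k in keys}
    sizes = dict(a.chrom_sizes)
    sizes.update(b.chrom_sizes)
    return DiffBinMatrix(
        sample_a=a.sample_id, sample_b=b.sample_id, spec=a.spec,
        chrom_sizes=sizes, diff=diff,
        unique5_a=dict(a.unique5), unique5_b=dict(b.unique5),
    )
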