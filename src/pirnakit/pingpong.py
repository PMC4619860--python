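"""Opposite-strand 5'-overlap (ping-pong) signature analysis.

The ping-pong amplification cycle produces sense/antisense piRNA pairs
whose 5' ends overlap by exactly 10 nt. For a plus-strand read P and a
minus-strand read M on one chromosome the 5'-to-5' span is
o = M.end - P.start (half-open coordinates); a pair is counted at overlap
o when 1 <= o <= o_max and the overlap region [P.start, M.end) lies within
both reads' spans, i.e. o <= min(len(P), len(M)). The ping-pong Z score
standardises the pair count at the focal overlap (10 nt) against the other
overlap lengths in a background window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationIndex, classify_pirna
from .core import AlignedRead, FilterPolicy, SampleSet


@dataclass
class OverlapHistogram:
    """Pair counts per 5'-overlap length o in [1, o_max]."""

    o_max: int
    counts: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.o_max < 10:
            raise ValueError("o_max must be >= 10")
        for o in range(1, self.o_max + 1):
            self.counts.setdefault(o, 0.0)

    def __getitem__(self, o: int) -> float:
        return self.counts[o]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            overlap=sorted(self.counts),
            count=[self.counts[o] for o in sorted(self.counts)],
        ))


def five_prime_overlaps(
    sample: SampleSet,
    o_max: int = 20,
    policy: FilterPolicy = FilterPolicy(),
    weight_by_hits: bool = False,
) -> OverlapHistogram:
    """Histogram of opposite-strand 5'-overlap lengths over size-selected reads.

    Each unordered (plus, minus) pair is counted once; with
    ``weight_by_hits`` a pair contributes 1/(n_hits_P * n_hits_M) so
    multi-mapped reads are down-weighted instead of multiply counted.
    """
    hist = OverlapHistogram(o_max=o_max)
    plus: dict[str, list[tuple[int, int, int]]] = {}
    minus_by_end: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for r in sample.pirna_reads(policy):
        chrom = r.interval.chrom
        if r.strand == "+":
            plus.setdefault(chrom, []).append(
                (r.interval.start, len(r), r.n_hits))
        else:
            minus_by_end.setdefault(chrom, {}).setdefault(
                r.interval.end, []).append((len(r), r.n_hits))
    for chrom, preads in plus.items():
        ends = minus_by_end.get(chrom)
        if not ends:
            continue
        for start, lp, nh_p in preads:
            for o in range(1, min(o_max, lp) + 1):
                for lm, nh_m in ends.get(start + o, ()):
                    if lm >= o:
                        w = 1.0 / (nh_p * nh_m) if weight_by_hits else 1.0
                        hist.counts[o] += w
    return hist


@dataclass(frozen=True)
class PingPongResult:
    """Z score of the focal overlap against the background window."""

    histogram: OverlapHistogram
    focal: int
    window: tuple[int, ...]
    z: float
    focal_count: float
    background_mean: float
    background_sd: float


def pingpong_z(
    hist: OverlapHistogram,
    focal: int = 10,
    window: Optional[Sequence[int]] = None,
) -> PingPongResult:
    """z = (count[focal] - mean(background)) / sample SD of background.

    The background is every overlap length in ``window`` (default 1..20)
    other than the focal length; the SD uses the n-1 convention. A
    zero-variance background is a degenerate input and raises, never
    returning an infinite score.
    """
    window = tuple(window) if window is not None else tuple(range(1, 21))
    if focal not in window:
        raise ValueError("window must contain the focal overlap length")
    background = [hist[o] for o in window if o != focal]
    if len(background) < 3:
        raise ValueError("need >= 3 background overlap lengths")
    bg = np.array(background, dtype=float)
    sd = bg.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate background: zero variance across window")
    mean = bg.mean()
    z = (hist[focal] - mean) / sd
    return PingPongResult(
        histogram=hist, focal=focal, window=window, z=float(z),
        focal_count=float(hist[focal]), background_mean=float(mean),
        background_sd=float(sd),
    )


@dataclass(frozen=True)
class StringentPairCriteria:
    """Conjunctive criteria admitting a read pair as ping-pong derived.

    1) both reads 23-32 nt; 2) the primary is 1U and the secondary is 10A
    (``base_rule='or'`` relaxes this to either); 3) exact 10-nt 5' overlap;
    4) the primary maps sense, and the secondary antisense, to a repeat or
    protein-coding exon.
    """

    min_len: int = 23
    max_len: int = 32
    overlap: int = 10
    base_rule: str = "and"

    def __post_init__(self) -> None:
        if self.base_rule not in ("and", "or"):
            raise ValueError("base_rule must be 'and' or 'or'")


@dataclass(frozen=True)
class StringentPair:
    primary: AlignedRead
    secondary: AlignedRead
    feature_class: str  # 'repeat' or 'gene'


def _feature_orientation(read: AlignedRead, index: AnnotationIndex
                         ) -> dict[str, tuple[bool, bool]]:
    """Per feature class ('repeat', 'gene'): (has sense hit, has antisense hit)."""
    out = {}
    for layer, name in (("repeat", "repeat"), ("exon_coding", "gene")):
        sense = anti = False
        for _, _, strand, _ in index.hits(layer, read):
            if strand not in ("+", "-"):
                continue
            if strand == read.strand:
                sense = True
            else:
                anti = True
        out[name] = (sense, anti)
    return out


def stringent_pairs(
    sample: SampleSet,
    index: AnnotationIndex,
    criteria: StringentPairCriteria = StringentPairCriteria(),
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[StringentPair], dict]:
    """Find pairs meeting all stringent ping-pong criteria.

    Returns the accepted pairs and summary proportions: the fraction of all
    size-selected piRNA reads participating in accepted pairs, and the
    repeat-mapped vs gene-mapped primary/secondary splits.
    """
    selected = [r for r in sample.reads
                if criteria.min_len <= len(r) <= criteria.max_len]
    if not selected:
        raise ValueError("no size-selected reads")
    by_chrom_plus: dict[str, list[AlignedRead]] = {}
    minus_by_end: dict[tuple[str, int], list[AlignedRead]] = {}
    for r in selected:
        if r.strand == "+":
            by_chrom_plus.setdefault(r.interval.chrom, []).append(r)
        else:
            minus_by_end.setdefault((r.interval.chrom, r.interval.end), []) \
                .append(r)

    calls = {id(r): classify_pirna(r, policy) for r in selected}
    orient = {id(r): _feature_orientation(r, index) for r in selected}

    def admissible(primary: AlignedRead, secondary: AlignedRead
                   ) -> Optional[str]:
        cp, cs = calls[id(primary)], calls[id(secondary)]
        if criteria.base_rule == "and":
            if not (cp.is_primary and cs.is_secondary):
                return None
        else:
            if not (cp.is_primary or cs.is_secondary):
                return None
        op, os_ = orient[id(primary)], orient[id(secondary)]
        for fclass in ("repeat", "gene"):
            if op[fclass][0] and os_[fclass][1]:
                return fclass
        return None

    pairs: list[StringentPair] = []
    for chrom, preads in by_chrom_plus.items():
        for p in preads:
            o = criteria.overlap
            if len(p) < o:
                continue
            for m in minus_by_end.get((chrom, p.interval.start + o), ()):
                if len(m) < o:
                    continue
                fclass = admissible(p, m) or admissible(m, p)
                if fclass:
                    # role order: the read that passed as primary first
                    if admissible(p, m):
                        pairs.append(StringentPair(p, m, fclass))
                    else:
                        pairs.append(StringentPair(m, p, fclass))
    in_pairs = {id(p.primary) for p in pairs} | {id(p.secondary) for p in pairs}
    n = len(selected)

    def _distinct(role: str, fclass: str) -> int:
        return len({id(getattr(p, role)) for p in pairs
                    if p.feature_class == fclass})

    stats_out = dict(
        n_pairs=len(pairs),
        n_reads_in_pairs=len(in_pairs),
        prop_pingpong=len(in_pairs) / n,
        prop_primary_repeat=_distinct("primary", "repeat") / n,
        prop_secondary_repeat=_distinct("secondary", "repeat") / n,
        prop_primary_gene=_distinct("primary", "gene") / n,
        prop_secondary_gene=_distinct("secondary", "gene") / n,
    )
    return pairs, stats_out
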