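"""Synthetic small-RNA library generator with ground truth.

Builds a toy genome with piRNA-cluster / repeat / gene annotation and emits
aligned-read libraries that emulate the statistical structure of wild-type
and Henmt1-mutant germ-cell small-RNA populations:

* 23-32 nt reads with a configurable length mixture — wild type unimodal at
  30 nt, mutant bimodal with modes at 26 and 30 nt;
* configurable 5'/3' truncation of a longer source species;
* single-base non-templated 3' adenylation / uridylation (a degradation
  mark detected downstream as a terminal reference mismatch);
* a 1U bias at the source 5' end (primary piRNAs);
* opposite-strand ping-pong partners with exact 10-nt 5' overlaps, planted
  sense/antisense over repeats or coding exons so they satisfy the
  stringent pair criteria;
* placement across annotation categories with a configurable sense /
  antisense ratio over stranded features.

Every emitted read carries a ground-truth record, so each downstream
estimator (tailing rate, truncation histogram, ping-pong fraction,
annotation summary) can be tested as parameter recovery. The generator is
fully deterministic under a fixed seed.

Tailing is modelled as length-neutral terminal-base replacement (trim one
base, then add the tail), so the length mixture describes emitted lengths
exactly; the assay downstream inspects a single terminal base either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import AlignedRead, GenomicInterval, SampleSet, revcomp
from .features import AnnotationSet, GeneModel

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CATEGORIES = (
    "piRNA_cluster",
    "repeat",
    "exon_coding",
    "exon_noncoding",
    "intron",
    "intergenic",
)


def _default_category_weights() -> dict[str, float]:
    # bulk of adult (pachytene) piRNAs arise from dedicated clusters and
    # intergenic space; genic and repeat-derived reads are minorities
    return {
        "piRNA_cluster": 0.55,
        "intergenic": 0.25,
        "intron": 0.06,
        "exon_coding": 0.05,
        "exon_noncoding": 0.04,
        "repeat": 0.05,
    }


@dataclass
class SyntheticConfig:
    """Parameters of the toy genome and of one simulated library.

    ``length_mixture`` is a list of ``(mode, weight, spread)`` triples; the
    emitted-length pmf is a discretised Gaussian mixture over
    ``[emit_min_len, emit_max_len]``. ``trunc3_dist``/``trunc5_dist`` map a
    truncation amount (bases) to its probability. ``tail_A_rate`` and
    ``tail_U_rate`` are the per-read probabilities of a single non-templated
    terminal A or U. ``pingpong_pair_frac`` is the fraction of reads emitted
    as members of opposite-strand pairs with exact 10-nt 5' overlaps.
    """

    seed: int = 0
    # genome shape
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_clusters_per_chrom: int = 3
    cluster_length: int = 40_000
    n_repeats_per_chrom: int = 12
    repeat_length: int = 400
    n_genes_per_chrom: int = 6
    gene_length: int = 12_000
    n_exons_per_gene: int = 3
    # library shape
    n_reads: int = 10_000
    sample_id: str = "synthetic"
    condition: str = "wild_type"
    cell_type: str = "spermatocyte"
    replicate: int = 0
    length_mixture: tuple[tuple[int, float, float], ...] = ((30, 1.0, 1.0),)
    emit_min_len: int = 23
    emit_max_len: int = 32
    trunc3_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    trunc5_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    tail_A_rate: float = 0.0
    tail_U_rate: float = 0.0
    frac_primary_1U: float = 0.85
    pingpong_pair_frac: float = 0.0
    antisense_frac: float = 0.2
    category_weights: Mapping[str, float] = field(
        default_factory=_default_category_weights
    )
    # grid placement at non-overlapping loci (used for truncation studies
    # where each short read must have a unique containing source)
    tile_loci: bool = False
    tile_step: int = 64

    def __post_init__(self) -> None:
        for rate in (self.tail_A_rate, self.tail_U_rate,
                     self.frac_primary_1U, self.pingpong_pair_frac,
                     self.antisense_frac):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.tail_A_rate + self.tail_U_rate > 1.0:
            raise ValueError("tail_A_rate + tail_U_rate must be <= 1")
        w = sum(weight for _, weight, _ in self.length_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")
        for dist in (self.trunc3_dist, self.trunc5_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("truncation distribution must sum to 1")


def wildtype_config(**overrides) -> SyntheticConfig:
    """Wild-type library: unimodal 30-nt piRNA pool, low tailing, active
    ping-pong."""
    base = dict(
        condition="wild_type",
        sample_id="wt",
        length_mixture=((30, 1.0, 1.0),),
        tail_A_rate=0.02,
        tail_U_rate=0.01,
        pingpong_pair_frac=0.2,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def mutant_config(**overrides) -> SyntheticConfig:
    """Henmt1-mutant-like library: bimodal length profile (reduced 30-nt
    peak, second peak at 26 nt), elevated 3' tailing, reduced ping-pong."""
    base = dict(
        condition="mutant",
        sample_id="mut",
        length_mixture=((30, 0.55, 1.0), (26, 0.45, 1.0)),
        tail_A_rate=0.10,
        tail_U_rate=0.05,
        pingpong_pair_frac=0.1,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# ---------------------------------------------------------------------------
# genome + annotation


def _gene_model(gene_id: str, chrom: str, start: int, length: int,
                n_exons: int, strand: str, coding: bool) -> GeneModel:
    unit = length // (2 * n_exons - 1)
    if unit < 6:
        raise ValueError("gene too short for requested exon count")
    exons = []
    for k in range(n_exons):
        a = start + 2 * k * unit
        exons.append(GenomicInterval(chrom, a, a + unit, strand))
    gene_iv = GenomicInterval(chrom, start, start + length, strand)
    if not coding:
        return GeneModel(gene_id, gene_iv, tuple(exons), coding=False)
    # split terminal exons (in transcript orientation) into UTR and CDS
    tx_exons = exons if strand == "+" else list(reversed(exons))
    cds, utr5, utr3 = [], [], []
    for k, e in enumerate(tx_exons):
        first, last = k == 0, k == len(tx_exons) - 1
        half = e.length // 2
        third = e.length // 3
        if first and last:
            if strand == "+":
                utr5.append(GenomicInterval(chrom, e.start, e.start + third, strand))
                cds.append(GenomicInterval(chrom, e.start + third, e.end - third, strand))
                utr3.append(GenomicInterval(chrom, e.end - third, e.end, strand))
            else:
                utr3.append(GenomicInterval(chrom, e.start, e.start + third, strand))
                cds.append(GenomicInterval(chrom, e.start + third, e.end - third, strand))
                utr5.append(GenomicInterval(chrom, e.end - third, e.end, strand))
        elif first:
            if strand == "+":
                utr5.append(GenomicInterval(chrom, e.start, e.start + half, strand))
                cds.append(GenomicInterval(chrom, e.start + half, e.end, strand))
            else:
                cds.append(GenomicInterval(chrom, e.start, e.end - half, strand))
                utr5.append(GenomicInterval(chrom, e.end - half, e.end, strand))
        elif last:
            if strand == "+":
                cds.append(GenomicInterval(chrom, e.start, e.end - half, strand))
                utr3.append(GenomicInterval(chrom, e.end - half, e.end, strand))
            else:
                utr3.append(GenomicInterval(chrom, e.start, e.start + half, strand))
                cds.append(GenomicInterval(chrom, e.start + half, e.end, strand))
        else:
            cds.append(cdsiv := GenomicInterval(chrom, e.start, e.end, strand))
    return GeneModel(gene_id, gene_iv, tuple(exons), True,
                     tuple(cds), tuple(utr5), tuple(utr3))


def simulate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], AnnotationSet]:
    """Generate a random toy genome and a disjoint annotation layout.

    Clusters and genes are laid out in alternating slots spread evenly along
    each chromosome, with repeats tucked into the slot margins, so the three
    feature classes never overlap and every read's ground-truth category is
    unambiguous. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    ann = AnnotationSet()
    n_slots = config.n_clusters_per_chrom + config.n_genes_per_chrom
    if n_slots == 0:
        raise ValueError("need at least one cluster or gene slot")
    slot_len = config.chrom_length // n_slots
    feat_off = slot_len // 3
    if config.cluster_length > slot_len - feat_off - 1:
        raise ValueError("cluster_length exceeds chromosome slot capacity")
    if config.gene_length > slot_len - feat_off - 1:
        raise ValueError("gene_length exceeds chromosome slot capacity")
    if config.repeat_length > feat_off - 200:
        raise ValueError("repeat_length exceeds slot margin capacity")
    rep_per_slot = -(-config.n_repeats_per_chrom // n_slots)  # ceil
    gene_counter = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        arr = _BASES[rng.integers(0, 4, size=config.chrom_length)]
        genome[chrom] = "".join(arr)
        n_clusters = n_genes = n_repeats = 0
        for s in range(n_slots):
            s0 = s * slot_len
            strand = "+" if s % 2 == 0 else "-"
            # repeats in the slot margin before the main feature
            margin_lo, margin_hi = s0 + 100, s0 + feat_off - config.repeat_length
            k = 0
            while n_repeats < config.n_repeats_per_chrom and k < rep_per_slot:
                step = max((margin_hi - margin_lo) // rep_per_slot, config.repeat_length + 1)
                r0 = margin_lo + k * step
                if r0 + config.repeat_length > margin_hi + config.repeat_length:
                    break
                ann.repeats.append(
                    GenomicInterval(chrom, r0, r0 + config.repeat_length,
                                    "+" if (s + k) % 2 == 0 else "-")
                )
                n_repeats += 1
                k += 1
            f0 = s0 + feat_off
            # alternate clusters and genes across slots
            want_cluster = (s % 2 == 0 and n_clusters < config.n_clusters_per_chrom) or \
                n_genes >= config.n_genes_per_chrom
            if want_cluster and n_clusters < config.n_clusters_per_chrom:
                ann.clusters.append(
                    GenomicInterval(chrom, f0, f0 + config.cluster_length, ".")
                )
                n_clusters += 1
            elif n_genes < config.n_genes_per_chrom:
                coding = gene_counter % 3 != 2  # two of three genes coding
                ann.genes.append(
                    _gene_model(f"gene_{gene_counter}", chrom, f0,
                                config.gene_length, config.n_exons_per_gene,
                                strand, coding)
                )
                gene_counter += 1
                n_genes += 1
    return genome, ann


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class GroundTruth:
    """Per-read generative record; exactly one row per emitted read.

    Columns: read_id, chrom, start, end, strand, category, mrna_subtype,
    feature_strand, source_len, trunc5, trunc3, tail ('' | 'A' | 'U'),
    is_1U_source, is_10A_source, partner_id ('' when unpaired).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_paired(self) -> int:
        return int((self.table["partner_id"] != "").sum())

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts()


def _length_pmf(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(config.emit_min_len, config.emit_max_len + 1)
    p = np.zeros(len(lengths), dtype=float)
    for mode, weight, spread in config.length_mixture:
        p += weight * np.exp(-((lengths - mode) ** 2) / (2.0 * spread ** 2))
    return lengths, p / p.sum()


class _Regions:
    """Candidate placement regions per annotation category."""

    def __init__(self, genome: Mapping[str, str], ann: AnnotationSet,
                 min_len: int):
        self.by_cat: dict[str, list[tuple[GenomicInterval, str, str]]] = {
            c: [] for c in CATEGORIES
        }
        for iv in ann.clusters:
            self.by_cat["piRNA_cluster"].append((iv, ".", "none"))
        for iv in ann.repeats:
            self.by_cat["repeat"].append((iv, iv.strand, "none"))
        for g in ann.genes:
            if g.coding:
                for sub, name in ((g.utr5, "5'UTR"), (g.cds, "CDS"),
                                  (g.utr3, "3'UTR")):
                    for iv in sub:
                        if iv.length >= min_len:
                            self.by_cat["exon_coding"].append(
                                (iv, g.interval.strand, name))
            else:
                for iv in g.exons:
                    self.by_cat["exon_noncoding"].append(
                        (iv, g.interval.strand, "none"))
            for iv in g.introns:
                if iv.length >= min_len:
                    self.by_cat["intron"].append((iv, g.interval.strand, "none"))
        # intergenic = complement of all feature footprints
        footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        for iv in ann.clusters + ann.repeats:
            footprints[iv.chrom].append((iv.start, iv.end))
        for g in ann.genes:
            footprints[g.interval.chrom].append(
                (g.interval.start, g.interval.end))
        for chrom, seq in genome.items():
            spans = sorted(footprints[chrom])
            cursor = 0
            for a, b in spans + [(len(seq), len(seq))]:
                if a - cursor >= min_len + 40:
                    self.by_cat["intergenic"].append(
                        (GenomicInterval(chrom, cursor + 1, a - 1), ".", "none"))
                cursor = max(cursor, b)

    def pick(self, rng: np.random.Generator, category: str
             ) -> tuple[GenomicInterval, str, str]:
        regions = self.by_cat[category]
        if not regions:
            raise ValueError(f"no placement region for category {category!r}")
        return regions[rng.integers(0, len(regions))]


def _read_seq(genome: Mapping[str, str], chrom: str, start: int, end: int,
              strand: str) -> str:
    s = genome[chrom][start:end]
    return s if strand == "+" else revcomp(s)


def _sample_discrete(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    keys = sorted(dist)
    return int(keys[rng.choice(len(keys), p=[dist[k] for k in keys])])


def simulate_reads(
    config: SyntheticConfig,
    genome: Mapping[str, str],
    annotations: AnnotationSet,
) -> tuple[SampleSet, GroundTruth]:
    """Emit one aligned library plus its ground truth.

    Read sequences are genome substrings (reverse complemented on '-'),
    modified only by the configured truncation and single-base tailing; the
    tail base shows up as a terminal mismatch against the reference bases.
    Ping-pong pairs are planted sense/antisense over repeats or coding exons
    with exact 10-nt 5' overlaps, the primary forced 1U (which makes the
    secondary 10A by complementarity).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    lengths, pmf = _length_pmf(config)
    regions = _Regions(genome, annotations, min_len=config.emit_max_len + 8)
    cats = list(config.category_weights)
    cat_p = np.array([config.category_weights[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()

    reads: list[AlignedRead] = []
    records: list[dict] = []
    n_pair_reads = int(round(config.pingpong_pair_frac * config.n_reads))
    n_pairs = n_pair_reads // 2
    n_total = config.n_reads
    read_no = 0
    tile_cursor = 0
    chrom_names = sorted(genome)

    def sample_len() -> int:
        return int(lengths[rng.choice(len(lengths), p=pmf)])

    def sample_tail() -> str:
        u = rng.random()
        if u < config.tail_A_rate:
            return "A"
        if u < config.tail_A_rate + config.tail_U_rate:
            return "U"
        return ""

    def emit(chrom: str, start: int, end: int, strand: str, category: str,
             subtype: str, feature_strand: str, source_len: int, t5: int,
             t3: int, partner: str) -> str:
        nonlocal read_no
        seq = _read_seq(genome, chrom, start, end, strand)
        ref = seq
        tail = sample_tail()
        if tail:
            base = "A" if tail == "A" else "T"
            seq = seq[:-1] + base
        # source (pre-truncation) 5' end and source-space base 10
        src5 = start - t5 if strand == "+" else end - 1 + t5
        first_src = genome[chrom][src5] if strand == "+" else _COMP[genome[chrom][src5]]
        p10 = src5 + 9 if strand == "+" else src5 - 9
        b10 = genome[chrom][p10] if strand == "+" else _COMP[genome[chrom][p10]]
        rid = f"{config.sample_id}_r{read_no}"
        read_no += 1
        reads.append(
            AlignedRead(
                read_id=rid,
                seq=seq,
                interval=GenomicInterval(chrom, start, end, strand),
                strand=strand,
                mapq=60,
                n_hits=1,
                ref_bases=ref,
            )
        )
        records.append(dict(
            read_id=rid, chrom=chrom, start=start, end=end, strand=strand,
            category=category, mrna_subtype=subtype,
            feature_strand=feature_strand, source_len=source_len,
            trunc5=t5, trunc3=t3, tail=tail,
            is_1U_source=first_src == "T", is_10A_source=b10 == "A",
            partner_id=partner,
        ))
        return rid

    def place(region: GenomicInterval, length: int, strand: str,
              force_1U: Optional[bool]) -> int:
        """5'-anchored start within region; rejection-samples the source 5'
        base when a 1U status is requested."""
        lo, hi = region.start, region.end - length
        if hi <= lo:
            raise ValueError("requested read length exceeds source locus length")
        for _ in range(64):
            start = int(rng.integers(lo, hi + 1))
            if force_1U is None:
                return start
            pos5 = start if strand == "+" else start + length - 1
            base = genome[region.chrom][pos5]
            is_u = (base == "T") if strand == "+" else (base == "A")
            if is_u == force_1U:
                return start
        return start  # fall back to the last draw

    pair_regions = regions.by_cat["repeat"] + regions.by_cat["exon_coding"]

    # --- planted ping-pong pairs -----------------------------------------
    for _ in range(n_pairs):
        if not pair_regions:
            raise ValueError("ping-pong pairs need repeat or coding-exon regions")
        region, feat_strand, subtype = pair_regions[rng.integers(0, len(pair_regions))]
        cat = "repeat" if subtype == "none" else "exon_coding"
        p_strand = feat_strand if feat_strand in ("+", "-") else "+"
        lp, lm = sample_len(), sample_len()
        t3p = _sample_discrete(rng, config.trunc3_dist)
        t3m = _sample_discrete(rng, config.trunc3_dist)
        start = place(region, lp, p_strand, force_1U=True)
        if p_strand == "+":
            p_iv = (start, start + lp - t3p)
            m_iv = (start + 10 - lm, start + 10 + t3m)  # then truncate 3'
            m_iv = (m_iv[0] + t3m, start + 10)
            m_strand = "-"
        else:
            e = start + lp
            p_iv = (start + t3p, e)
            m_iv = (e - 10, e - 10 + lm - t3m)
            m_strand = "+"
        if m_iv[0] < 0 or m_iv[1] > len(genome[region.chrom]):
            continue  # rare edge clipping; keep the library slightly smaller
        rid_p = emit(region.chrom, p_iv[0], p_iv[1], p_strand, cat, subtype,
                     feat_strand, lp, 0, t3p, partner=f"pending")
        rid_m = emit(region.chrom, m_iv[0], m_iv[1], m_strand, cat, subtype,
                     feat_strand, lm, 0, t3m, partner=rid_p)
        records[-2]["partner_id"] = rid_m

    # --- singleton reads ---------------------------------------------------
    n_singletons = n_total - len(reads)
    for _ in range(n_singletons):
        L = sample_len()
        t5 = _sample_discrete(rng, config.trunc5_dist)
        t3 = _sample_discrete(rng, config.trunc3_dist)
        Lf = L - t5 - t3
        if Lf < 11:
            raise ValueError("truncation leaves read shorter than 11 nt")
        if config.tile_loci:
            # non-overlapping grid, round-robin over chromosomes
            chrom = chrom_names[tile_cursor % len(chrom_names)]
            pos = 100 + (tile_cursor // len(chrom_names)) * config.tile_step
            tile_cursor += 1
            if pos + config.emit_max_len + 2 > len(genome[chrom]):
                raise ValueError("tile placement exceeds chromosome length")
            strand = "+" if tile_cursor % 2 else "-"
            src_start = pos
            cat, subtype, feat_strand = "intergenic", "none", "."
        else:
            cat = cats[rng.choice(len(cats), p=cat_p)]
            region, feat_strand, subtype = regions.pick(rng, cat)
            if feat_strand in ("+", "-"):
                anti = rng.random() < config.antisense_frac
                strand = feat_strand if not anti else ("-" if feat_strand == "+" else "+")
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            force = rng.random() < config.frac_primary_1U
            src_start = place(region, L, strand, force_1U=force)
        if strand == "+":
            start, end = src_start + t5, src_start + L - t3
        else:
            start, end = src_start + t3, src_start + L - t5
        emit(chrom if config.tile_loci else region.chrom, start, end, strand,
             cat, subtype, feat_strand, L, t5, t3, partner="")

    sample = SampleSet(
        sample_id=config.sample_id,
        condition=config.condition,
        cell_type=config.cell_type,
        replicate=config.replicate,
        reads=reads,
    )
    truth = GroundTruth(pd.DataFrame.from_records(records))
    return sample, truth


def derive_truncated(
    sample: SampleSet,
    trunc3_dist: Mapping[int, float],
    trunc5_dist: Mapping[int, float] | None = None,
    seed: int = 0,
    sample_id: Optional[str] = None,
) -> tuple[SampleSet, pd.DataFrame]:
    """Derive a shortened library by truncating each read of ``sample``.

    Models the mutant situation in which short piRNAs are nucleolytic
    truncation products of a long source pool: each output read is the input
    read with ``k3`` bases removed from the 3' end (and optionally ``k5``
    from the 5' end), drawn from the given distributions. Returns the new
    sample plus a table of applied truncations per read.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    trunc5_dist = trunc5_dist or {0: 1.0}
    out_reads = []
    rows = []
    for read in sample.reads:
        k3 = _sample_discrete(rng, trunc3_dist)
        k5 = _sample_discrete(rng, trunc5_dist)
        L = len(read.seq) - k3 - k5
        if L < 1:
            raise ValueError(f"read {read.read_id}: truncation exceeds length")
        seq = read.seq[k5:len(read.seq) - k3]
        ref = None
        if read.ref_bases is not None:
            ref = read.ref_bases[k5:len(read.ref_bases) - k3]
        iv = read.interval
        if read.strand == "+":
            new_iv = GenomicInterval(iv.chrom, iv.start + k5, iv.end - k3, "+")
        else:
            new_iv = GenomicInterval(iv.chrom, iv.start + k3, iv.end - k5, "-")
        rid = f"{read.read_id}.t"
        out_reads.append(
            AlignedRead(rid, seq, new_iv, read.strand, read.mapq,
                        read.n_hits, ref)
        )
        rows.append(dict(read_id=rid, source_id=read.read_id,
                         trunc5=k5, trunc3=k3))
    out = SampleSet(
        sample_id=sample_id or f"{sample.sample_id}_trunc",
        condition=sample.condition,
        cell_type=sample.cell_type,
        replicate=sample.replicate,
        reads=out_reads,
    )
    return out, pd.DataFrame.from_records(rows)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
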