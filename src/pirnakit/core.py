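"""Core domain types and alignment ingestion.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted on ingestion. Read sequences are stored in *read space*, i.e. the
5'->3' orientation of the sequenced RNA: for minus-strand alignments this is
the reverse complement of the SAM SEQ field. Reference bases over the aligned
span are stored in the same orientation so that terminal-base comparisons
(3'-tailing) and positional base tests (1U/10A) can be made directly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: placeholder used in ``ref_bases`` where a read base has no aligned
#: reference base (soft clip or insertion)
GAP = "-"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True when ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """One aligned small-RNA read.

    ``seq`` and ``ref_bases`` are read-space strings (5'->3' of the RNA);
    ``ref_bases`` carries :data:`GAP` where a read base is unaligned.
    """

    read_id: str
    seq: str
    interval: GenomicInterval
    strand: str
    mapq: int = 0
    n_hits: int = 1
    ref_bases: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.read_id} has empty sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id} has strand {self.strand!r}")
        if self.ref_bases is not None and len(self.ref_bases) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: ref_bases length != seq length"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' end (strand-aware)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the 3' end (strand-aware)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start


def five_prime(read: AlignedRead) -> int:
    """Genomic 5'-end position: ``start`` on '+', ``end - 1`` on '-'.

    Invariant under 3'-end truncation of the same alignment, which is why
    unique 5' ends serve as a proxy for distinct piRNA species.
    """
    return read.five_prime


@dataclass(frozen=True)
class FilterPolicy:
    """Read-retention policy applied at ingestion and piRNA calling.

    piRNAs are defined as 23-32 nt; multi-mapping reads are retained up to
    ``max_hits`` reported alignments (the mapper-side cap used to build the
    retained universe). ``min_mapq`` defaults to 0 and is exposed as
    configuration. ``require_aligned_3prime`` excludes reads whose 3'-terminal
    base is soft clipped from the tailing analysis.
    """

    pirna_min_len: int = 23
    pirna_max_len: int = 32
    min_mapq: int = 0
    max_hits: int = 3
    require_aligned_3prime: bool = True

    def __post_init__(self) -> None:
        if self.pirna_min_len > self.pirna_max_len:
            raise ValueError("pirna_min_len > pirna_max_len")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    def is_pirna_length(self, n: int) -> bool:
        return self.pirna_min_len <= n <= self.pirna_max_len


@dataclass
class SampleSet:
    """A labelled collection of aligned reads from one library."""

    sample_id: str
    condition: str = ""
    cell_type: str = ""
    replicate: int = 0
    reads: list[AlignedRead] = field(default_factory=list)
    filter_tally: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def require_nonempty(self, what: str = "analysis") -> None:
        if not self.reads:
            raise ValueError(f"sample {self.sample_id}: no reads for {what}")

    def pirna_reads(self, policy: FilterPolicy) -> list[AlignedRead]:
        """Reads passing the piRNA length criterion (size selection)."""
        return [r for r in self.reads if policy.is_pirna_length(len(r))]

    def subset(self, reads: Iterable[AlignedRead], suffix: str = "subset") -> "SampleSet":
        return SampleSet(
            sample_id=f"{self.sample_id}:{suffix}",
            condition=self.condition,
            cell_type=self.cell_type,
            replicate=self.replicate,
            reads=list(reads),
        )


def _n_hits(aln: pysam.AlignedSegment) -> int:
    """Reported alignment count: NH tag, else BWA's X0(+X1), else 1."""
    if aln.has_tag("NH"):
        return int(aln.get_tag("NH"))
    n = 0
    for tag in ("X0", "X1"):
        if aln.has_tag(tag):
            n += int(aln.get_tag(tag))
    return n if n > 0 else 1


def _ref_bases_genomic(
    aln: pysam.AlignedSegment,
    fasta: Optional["pyfaidx.Fasta"],  # noqa: F821 - optional import
) -> list[str]:
    """Per-query-base reference bases in genomic orientation (GAP if none)."""
    out = [GAP] * aln.query_length
    try:
        pairs = aln.get_aligned_pairs(with_seq=True)
        has_md = True
    except ValueError:
        pairs = aln.get_aligned_pairs()
        has_md = False
    if has_md:
        for item in pairs:
            qpos, rpos = item[0], item[1]
            base = item[2] if len(item) > 2 else None
            if qpos is not None and rpos is not None and base is not None:
                out[qpos] = base.upper()
        return out
    if fasta is None:
        raise ValueError(
            f"read {aln.query_name}: no MD tag and no reference FASTA "
            "provided; cannot reconstruct reference bases"
        )
    chrom = aln.reference_name
    if chrom not in fasta:
        raise ValueError(
            f"read {aln.query_name}: contig {chrom!r} absent from reference"
        )
    for qpos, rpos in pairs:
        if qpos is not None and rpos is not None:
            out[qpos] = str(fasta[chrom][rpos]).upper()
    return out


def load_alignments(
    path: str | Path,
    policy: FilterPolicy = FilterPolicy(),
    reference: str | Path | None = None,
    sample_id: Optional[str] = None,
    condition: str = "",
    cell_type: str = "",
    replicate: int = 0,
) -> SampleSet:
    """Read a SAM/BAM file into a :class:`SampleSet`, applying the policy.

    Unmapped reads and reads failing the mapq / reported-hit-count policy are
    dropped and tallied by reason. Each retained alignment becomes one
    :class:`AlignedRead` (no fractional multi-mapper weighting). Reference
    bases come from the MD tag when present, else from ``reference``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fasta = None
    if reference is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(reference))
    sample = SampleSet(
        sample_id=sample_id or path.stem,
        condition=condition,
        cell_type=cell_type,
        replicate=replicate,
    )
    tally = sample.filter_tally
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_id < 0:
                tally["unmapped"] += 1
                continue
            if aln.mapping_quality < policy.min_mapq:
                tally["low_mapq"] += 1
                continue
            if _n_hits(aln) > policy.max_hits:
                tally["too_many_hits"] += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            ref = _ref_bases_genomic(aln, fasta)
            seq = aln.query_sequence.upper()
            ref_str = "".join(ref)
            if strand == "-":
                # read space = reverse complement of SAM orientation
                seq = revcomp(seq)
                ref_str = revcomp(ref_str)
            sample.reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    seq=seq,
                    interval=GenomicInterval(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        strand,
                    ),
                    strand=strand,
                    mapq=aln.mapping_quality,
                    n_hits=_n_hits(aln),
                    ref_bases=ref_str,
                )
            )
            tally["retained"] += 1
    for reason, n in sorted(tally.items()):
        logger.info("%s: %s reads %s", sample.sample_id, n, reason)
    return sample


def _md_from_bases(seq: str, ref: str) -> Optional[str]:
    """MD tag for a pure-match CIGAR alignment (None if any base unaligned)."""
    if GAP in ref:
        return None
    run = 0
    parts: list[str] = []
    for q, r in zip(seq, ref):
        if q == r:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


def write_sam(
    sample: SampleSet,
    path: str | Path,
    reference_lengths: Mapping[str, int],
) -> None:
    """Write a SampleSet as a SAM file (inverse of :func:`load_alignments`).

    Only gapless alignments (CIGAR ``<len>M``) are representable, which covers
    everything this toolkit produces; an MD tag is emitted when the reference
    bases are fully aligned so the file reloads without a FASTA.
    """
    names = list(reference_lengths)
    header = pysam.AlignmentHeader.from_references(
        names, [reference_lengths[n] for n in names]
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in sample.reads:
            if len(read.seq) != read.interval.length:
                raise ValueError(
                    f"read {read.read_id}: gapped alignment not representable"
                )
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            # back to SAM orientation
            seq = read.seq if read.strand == "+" else revcomp(read.seq)
            ref = read.ref_bases
            if ref is not None and read.strand == "-":
                ref = revcomp(ref)
            a.query_sequence = seq
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = names.index(read.interval.chrom)
            a.reference_start = read.interval.start
            a.mapping_quality = read.mapq
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            tags = [("NH", read.n_hits)]
            if ref is not None:
                md = _md_from_bases(seq, ref)
                if md is not None:
                    tags.append(("MD", md))
                tags.append(
                    ("NM", sum(1 for q, r in zip(seq, ref) if q != r))
                )
            a.set_tags(tags)
            out.write(a)
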