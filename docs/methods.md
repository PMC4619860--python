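# Methods

This note documents the models, conventions and numerical choices behind
`pirnakit`, and what the synthetic-data validation does and does not show.

## Coordinates, strands, and read space

All genomic intervals are 0-based half-open. SAM's 1-based positions are
converted at ingestion. Read sequences are stored in *read space* — the
5'→3' orientation of the sequenced RNA — so a minus-strand alignment's
sequence is the reverse complement of the SAM SEQ field, and the reference
bases over the aligned span are complemented into the same orientation.
This is deliberate: piRNA nucleotide biases (1U, 10A) and 3'-terminal
tailing are properties of the RNA, not of the reference strand. The
genomic 5' end of an alignment is `start` on the plus strand and
`end − 1` on the minus strand; it is invariant under 3' truncation, which
is what makes distinct 5' ends a usable proxy for distinct piRNA species.

Reference bases come from the MD tag when present, else from the supplied
FASTA; a read with neither is an error naming the read. Multi-mapper
counts come from the NH tag, else BWA's X0+X1, else 1; each retained
alignment contributes one count (no fractional weighting). The default
retention policy is mapq ≥ 0 (exposed as configuration; no published
cutoff exists for this assay class) and at most 3 reported alignments,
the mapper-side cap used to build the retained universe.

## piRNA calling and annotation

A read is a piRNA when 23 ≤ length ≤ 32; primary (1U) and secondary (10A)
flags are evaluated 1-based in read space and a read may carry both. Where
an exclusive primary/secondary split is needed, primary wins by default
(configurable) — no principled precedence exists, so both overlapping and
exclusive tallies are emitted.

Annotation is exclusive with priority piRNA cluster > repeat > coding
exon > non-coding exon > intron, ≥ 1 bp of overlap, intergenic otherwise.
Intron intervals are computed as gene body minus exons rather than read
from the annotation. Cluster reads are candidate piRNAs and are
re-annotated against the remaining layers for a secondary category;
coding-exon reads get a 5'UTR/CDS/3'UTR subtype. Antisense status comes
from the largest-overlap feature of the winning layer; exact ties resolve
to sense (conservative), and unstranded features are never antisense.

## 3'-terminal tailing

Uridylation is counted only when the terminal reference base is not T —
only then can a terminal T in the read be recognised as non-templated —
and adenylation likewise with A. The *informative* denominator (terminal
reference base ≠ tested base) is the primary report because it is the
population over which modification is decidable; the all-piRNA-reads
denominator is emitted alongside for comparability. Soft-clipped 3'
termini are excluded and tallied by default. Genotype comparisons use a
two-sided Welch t-test on per-replicate percentages.

## Binning and denesting

Bins follow reference coordinates from 0 with a default width of 10 Mbp;
the final partial bin is kept and per-bp values divide by its actual width
(flagged in output metadata). Lengths are stratified over 20–35 nt with
long (28–32) and short (23–27) pool sums; out-of-range alignments are
tallied separately, never dropped silently. Unique 5' ends are keyed by
(chrom, strand, position) — strand-aware because 5' ends are
strand-defined. Denesting first removes duplicate intervals, then keeps
intervals with no distinct containing interval (B contains A iff
B.start ≤ A.start and A.end ≤ B.end and B ≠ A), implemented as a single
sweep over intervals sorted by (start asc, end desc) and verified against
an O(n²) containment scan. Differential matrices subtract counts
elementwise (B − A) under an identical binning spec — a spec mismatch is
an error — while 5'-end counts stay per-sample.

## Truncation (overlap-end) profiling

The long pool is deduplicated by (chrom, strand, start, length) and
optionally denested. In the default contained mode each short alignment
is scored against the single longest long alignment that completely
contains it and is longer; ties break to the smallest start, then input
order, so runs are deterministic. Containment prevents truncated long
forms from multiplying counts and abolishes spurious positive "negative
truncation" from partial overlaps; because that multiplicity question is
real, an all-containing mode records every container, and a non-contained
mode (≥ 1 bp overlap) permits positive deltas. Sign convention: on the
plus strand Δ5 = L.start − S.start and Δ3 = S.end − L.end, mirrored on
the minus strand, so shortening is negative at the shortened end and a
short read identical to its partner scores (0, 0).

`compare_ends` is a hand-implemented Welch two-sample t-test on |Δ3| vs
|Δ5|: Welch–Satterthwaite degrees of freedom, two-sided p, and the 95%
difference-of-means CI. It is cross-checked in the tests against scipy's
independent implementation at 1e-9 relative tolerance. Degenerate inputs
(zero variance in both samples, equal means) return t = 0, p = 1 rather
than NaN. The genotype comparison reports the change in mean |Δ| per end
(B − A) with the same Welch CI plus per-length-change proportion
differences. The CI is reported as a difference in bases; a ratio reading
of published interval styles exists but is not the default.

## Ping-pong signature

For plus read P and minus read M on one chromosome, the 5'-overlap is
o = M.end − P.start, counted when 1 ≤ o ≤ o_max and o ≤ min(|P|, |M|)
(the overlap region must lie within both reads); each unordered pair
counts once, with an option to weight pairs by 1/(NH_P·NH_M). The Z score
at the focal overlap (10 nt) uses all other lengths in a 1–20 window as
background with the sample (n−1) SD; window and SD convention are
config-exposed since published analyses vary, and a zero-variance
background raises rather than returning ±∞. The stringent pair filter
requires, conjunctively: both reads 23–32 nt; primary 1U **and**
secondary 10A (a flag restores the literal "or" reading); exact 10-nt 5'
overlap; primary sense and secondary antisense to a repeat or coding
exon.

## The synthetic generator

The generator emulates the statistical structure of wild-type and
*Henmt1*-mutant germ-cell libraries, not their genomic content. Defaults:

| parameter | wild type | mutant | why |
|---|---|---|---|
| length mixture (mode, weight, σ) | (30, 1.0, 1.0) | (30, 0.55, 1.0) + (26, 0.45, 1.0) | unimodal 30-nt vs bimodal 26/30-nt profiles of adult germ-cell piRNA pools |
| tail_A_rate / tail_U_rate | 0.02 / 0.01 | 0.10 / 0.05 | low baseline vs elevated tailing of unmethylated piRNAs |
| pingpong_pair_frac | 0.2 | 0.1 | active vs weakened ping-pong amplification |
| frac_primary_1U | 0.85 | 0.85 | strong 1U bias of primary piRNAs |
| antisense_frac | 0.2 | 0.2 | minority antisense placement over stranded features |

The toy genome (2 × 1 Mbp by default) lays clusters and genes into
alternating slots with repeats in the slot margins, so feature classes
never overlap and every read's ground-truth category is unambiguous;
coding genes carry exon/CDS/UTR substructure with implied introns. Reads
are genome substrings (reverse complemented on the minus strand) modified
only by configured truncation and tailing. Tailing is modelled as
length-neutral terminal-base replacement (trim one base, then append the
tail): the downstream assay inspects a single terminal base either way,
and this keeps the length mixture exact. The 1U fraction is enforced by
rejection-sampling source loci (the 5' genome base), so it is exact in
expectation for singletons; planted pair secondaries are unconstrained at
position 1, which leaves the whole-library 1U fraction slightly below the
configured value when pairs are planted. Ping-pong pairs are planted over
repeats or coding exons, primary sense and 1U-forced — which makes the
secondary 10A automatically, by complementarity of position 10 with the
primary's position 1 — with exact 10-nt 5' overlaps that survive
3'-truncation (5' truncation is not applied to pair members, as it would
move the 5' ends the definition depends on).

A tiled placement mode (`tile_loci`) puts reads at non-overlapping grid
loci; combined with a degenerate 32-nt length mixture and
`derive_truncated` (which shortens each read by known, recorded amounts),
it yields truncation studies where every short read has exactly one
containing source, making exact histogram recovery well-defined.

What the generator does **not** model: sequencing error, base-quality
structure, PCR duplicates, multi-base tails, multi-mapping ambiguity, or
the genomic sequence composition of real piRNA clusters. Passing
recovery tests therefore demonstrates the correctness of the analysis
arithmetic under the stated generative model, not robustness to real
library artefacts.

## Validation design and problem sizes

Every estimator is validated as parameter recovery against ground truth
(tail rates within 3 binomial standard errors at n = 10,000; truncation
histograms exactly at n = 2,000 pairs; planted pair recovery), and every
nontrivial combinatorial step against an independent brute-force oracle
(denesting vs an O(n²) containment scan over 200 random trials of up to
500 intervals; containment assignment vs exhaustive all-pairs search;
overlap histograms vs all-pairs enumeration on 200-read inputs). The
ping-pong score is calibrated on pair-free libraries (|z| < 3 in ≥ 95 of
100 seeded 2,000-read runs) and powered on planted-pair libraries
(z > 5 in 20 of 20 runs at n = 5,000, pair fraction 0.3). These sizes
were chosen to give stable statistics at interactive run times; all
randomness is seeded and runs are deterministic.

## Known limitations

- Sequence-based piRNA criteria beyond length and 1U/10A are not modelled;
  published pipelines sometimes apply additional composition filters whose
  definitions are not public.
- Fractional multi-mapper weighting is available only in the ping-pong
  counting, not in binning.
- The intron layer assumes gene models whose exons lie within the gene
  body; trans-spliced or discontiguous models are out of scope.
- GFF3 I/O covers the feature types this toolkit emits (clusters, repeats,
  gene/exon/CDS/UTR with Parent links), not arbitrary GFF3 dialects.
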