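# pirnakit

Small-RNA sequence analysis for piRNA biogenesis studies.

PIWI-interacting RNAs (piRNAs) are 23–32 nt germ-line small RNAs whose 3'
ends are stabilised by 2'-O-methylation. When that methylation is lost —
as in *Henmt1* mutant mouse germ cells — piRNAs become substrates for
non-templated 3' tailing (uridylation/adenylation) and 3'→5' exonucleolytic
trimming, the population shortens, and the ping-pong amplification signature
weakens. `pirnakit` provides the sequence-level analyses needed to measure
all of this from aligned small-RNA reads, plus a ground-truthed synthetic
library generator so every stage can be validated without any sequencing
data.

## What it computes

Given SAM/BAM alignments, a FASTA reference and GFF3/BED annotation:

- **piRNA classification** — length selection (23–32 nt), primary (1U:
  uridine at read position 1) and secondary (10A: adenine at read position
  10) calls, evaluated on the RNA (read-space) sequence.
- **Hierarchical annotation** — exclusive category per read with priority
  piRNA cluster > repeat > coding exon > non-coding exon > intron >
  intergenic (≥1 bp overlap), antisense flags, 5'UTR/CDS/3'UTR subtypes,
  and within-cluster secondary annotation.
- **Length distributions** — counts and percent-of-total piRNA reads per
  length, grouped by condition across replicates.
- **3' tailing** — a read is *uridylated* when its last base is T while the
  reference base at that position is not T (so the addition must be
  non-templated); adenylation likewise with A. Percentages are reported
  over informative reads (terminal reference base ≠ tested base) and over
  all piRNA reads.
- **Binned expression** — alignment tallies per 10-Mbp bin (configurable)
  stratified by read length (20–35 nt), long-pool (28–32 nt) and
  short-pool (23–27 nt) sums, and distinct-5'-end counts as a proxy for
  piRNA species, with optional interval-tree *denesting* (a 5' end counts
  only when its alignment is not fully encompassed by another).
  Differential mode subtracts two samples' tallies bin by bin.
- **Truncation profiling** — each short-pool alignment is assigned to the
  longest long-pool alignment that completely contains it; the signed
  end offsets (negative = shortening) quantify 5' vs 3' truncation, and a
  Welch two-sample t-test on |Δ3| vs |Δ5| with a 95% CI of the mean
  difference tests for 3' bias.
- **Ping-pong signature** — opposite-strand pair counts by 5'-overlap
  length; for plus read P and minus read M, o = M.end − P.start, counted
  when the overlap region lies within both reads. The Z score at the focal
  10-nt overlap is (count[10] − mean(background)) / SD(background) over a
  1–20 nt window. A stringent filter finds pairs that jointly satisfy
  size, 1U/10A, exact-10 overlap, and sense/antisense placement over
  repeats or coding genes.

## Worked example

```python
import pirnakit as pk

# a synthetic wild-type / mutant pair with known ground truth
cfg_wt = pk.wildtype_config(seed=1, n_reads=10_000)
cfg_mut = pk.mutant_config(seed=2, n_reads=10_000)
genome, annotation = pk.simulate_genome(cfg_wt)
wt, wt_truth = pk.simulate_reads(cfg_wt, genome, annotation)
mut, _ = pk.simulate_reads(cfg_mut, genome, annotation)

dist = pk.length_distribution(mut)
print(dist.loc[dist["percent"].idxmax(), "length"])   # 30
mods = pk.end_modification(mut)
print(round(mods.pct_uridylated, 2))                  # 4.88
z = pk.pingpong_z(pk.five_prime_overlaps(wt))
print(round(z.z, 1))                                  # 70.8
```

The mutant library keeps its main 30-nt peak but gains a second mode at
26 nt; its uridylation estimate (4.88% of informative reads) recovers the
configured 5% tail rate; and the wild-type ping-pong Z score of 70.8
reflects the planted 10-nt-overlap pairs standing far above the background
overlap counts.

The same stages are available from the shell:

```sh
pirnakit simulate --outdir out --seed 1 --n-reads 10000
pirnakit pingpong --alignments out/mut.sam --out pp.tsv --gff out/annotation.gff3
pirnakit trunc --alignments-long out/wt.sam --alignments-short out/mut.sam \
    --reference out/genome.fa --out trunc.csv
```

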