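"""Read-length distributions and 3'-terminal non-templated tailing.

Lengths are tallied over reads meeting the piRNA criteria and expressed as
percentages of total piRNA reads per sample; replicates carry condition
labels so they can be grouped for reporting.

Tailing (a degradation mark on piRNAs lacking 3' 2'-O-methylation) is
detected as a terminal reference mismatch: the last 3' base of each aligned
piRNA read is compared with the reference base at that position, in read
orientation. A read counts as uridylated when it ends in T while the
reference base is not T — only then is a non-templated addition
distinguishable from genome-encoded sequence — and adenylation is measured
the same way with A. Percentages are reported over the informative
denominator (terminal reference base != tested base) and, for
comparability, over all piRNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GAP, FilterPolicy, SampleSet


def length_distribution(
    sample: SampleSet,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Length histogram of piRNA reads as counts and percent of total.

    Returns a long-format frame with one row per length in
    ``[pirna_min_len, pirna_max_len]``; percentages sum to 100.
    Raises when the sample has no piRNA-length reads (never emits NaN).
    """
    reads = sample.pirna_reads(policy)
    if not reads:
        raise ValueError(
            f"sample {sample.sample_id}: no reads meet the piRNA length criteria"
        )
    lengths = np.array([len(r) for r in reads])
    rows = []
    total = len(lengths)
    for L in range(policy.pirna_min_len, policy.pirna_max_len + 1):
        c = int((lengths == L).sum())
        rows.append(dict(
            sample=sample.sample_id, condition=sample.condition,
            replicate=sample.replicate, length=L, count=c,
            percent=100.0 * c / total,
        ))
    return pd.DataFrame.from_records(rows)


def grouped_length_distribution(samples: list[SampleSet],
                                policy: FilterPolicy = FilterPolicy()
                                ) -> pd.DataFrame:
    """Replicate-level rows plus per-condition mean/SD of percent by length."""
    per_rep = pd.concat(
        [length_distribution(s, policy) for s in samples], ignore_index=True
    )
    grouped = (
        per_rep.groupby(["condition", "length"])["percent"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "percent_mean", "std": "percent_sd"})
    )
    return per_rep.merge(grouped, on=["condition", "length"])


@dataclass(frozen=True)
class EndModSummary:
    """Terminal adenylation / uridylation tallies for one sample.

    ``n_informative_X`` counts piRNA reads whose terminal *reference* base
    differs from X (so a terminal X in the read must be non-templated);
    ``n_excluded`` counts reads whose terminal base is unaligned (clipped)
    under ``require_aligned_3prime``.
    """

    sample_id: str
    condition: str
    n_pirna: int
    n_informative_A: int
    n_adenylated: int
    n_informative_U: int
    n_uridylated: int
    n_excluded: int = 0

    @property
    def pct_adenylated(self) -> float:
        """Adenylated percent of informative reads."""
        return 100.0 * self.n_adenylated / self.n_informative_A \
            if self.n_informative_A else 0.0

    @property
    def pct_uridylated(self) -> float:
        return 100.0 * self.n_uridylated / self.n_informative_U \
            if self.n_informative_U else 0.0

    @property
    def pct_adenylated_of_all(self) -> float:
        """Adenylated percent of all piRNA reads (alternative denominator)."""
        return 100.0 * self.n_adenylated / self.n_pirna if self.n_pirna else 0.0

    @property
    def pct_uridylated_of_all(self) -> float:
        return 100.0 * self.n_uridylated / self.n_pirna if self.n_pirna else 0.0

    def to_row(self) -> dict:
        return dict(
            sample=self.sample_id, condition=self.condition,
            n_pirna=self.n_pirna,
            n_informative_A=self.n_informative_A,
            n_adenylated=self.n_adenylated,
            pct_adenylated=self.pct_adenylated,
            pct_adenylated_of_all=self.pct_adenylated_of_all,
            n_informative_U=self.n_informative_U,
            n_uridylated=self.n_uridylated,
            pct_uridylated=self.pct_uridylated,
            pct_uridylated_of_all=self.pct_uridylated_of_all,
            n_excluded=self.n_excluded,
        )


def end_modification(
    sample: SampleSet,
    policy: FilterPolicy = FilterPolicy(),
) -> EndModSummary:
    """Detect non-templated terminal A/U over the sample's piRNA reads.

    Comparisons are made in read orientation (for minus-strand alignments
    the stored reference bases are already complemented). Reads whose
    3'-terminal base has no aligned reference base are excluded and tallied
    when ``policy.require_aligned_3prime`` (the default); otherwise such
    reads are simply uninformative for both tests.
    """
    n_pirna = 0
    n_inf_a = n_aden = n_inf_u = n_urid = n_excl = 0
    for read in sample.pirna_reads(policy):
        n_pirna += 1
        if read.ref_bases is None:
            raise ValueError(
                f"read {read.read_id}: reference bases unavailable for "
                "end-modification analysis"
            )
        last = read.seq[-1]
        ref_last = read.ref_bases[-1]
        if ref_last == GAP:
            n_excl += 1
            continue
        if ref_last != "A":
            n_inf_a += 1
            if last == "A":
                n_aden += 1
        if ref_last != "T":
            n_inf_u += 1
            if last == "T":
                n_urid += 1
    return EndModSummary(
        sample_id=sample.sample_id, condition=sample.condition,
        n_pirna=n_pirna, n_informative_A=n_inf_a, n_adenylated=n_aden,
        n_informative_U=n_inf_u, n_uridylated=n_urid, n_excluded=n_excl,
    )


def compare_modification(
    group_a: list[EndModSummary],
    group_b: list[EndModSummary],
    which: str = "adenylation",
) -> dict:
    """Two-sided Welch t-test on per-replicate modification percentages."""
    attr = "pct_adenylated" if which == "adenylation" else "pct_uridylated"
    a = np.array([getattr(s, attr) for s in group_a], dtype=float)
    b = np.array([getattr(s, attr) for s in group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    res = stats.ttest_ind(a, b, equal_var=False)
    return dict(
        which=which, mean_a=float(a.mean()), mean_b=float(b.mean()),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
    )


def end_modification_table(summaries: list[EndModSummary]) -> pd.DataFrame:
    return pd.DataFrame.from_records([s.to_row() for s in summaries])
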