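"""piRNA calling and exclusive hierarchical annotation."""

import numpy as np
import pytest

import pirnakit as pk
from pirnakit.annotate import PRIORITY
from pirnakit.features import AnnotationSet, GeneModel

from conftest import make_read


class TestClassifyPirna:
    @pytest.mark.parametrize("seq,is_pirna,is_primary,is_secondary", [
        ("T" + "C" * 29, True, True, False),            # 30 nt, 1U
        ("G" * 22, False, False, False),                # below 23 nt
        ("G" * 9 + "A" + "G" * 16, True, False, True),  # 26 nt, 10A only
        ("T" + "C" * 8 + "A" + "C" * 20, True, True, True),  # both flags
        ("G" * 33, False, False, False),                # above 32 nt
    ])
    def test_length_and_base_criteria(self, seq, is_pirna, is_primary,
                                      is_secondary):
        read = make_read(start=100, end=100 + len(seq), seq=seq)
        call = pk.classify_pirna(read)
        assert (call.is_pirna, call.is_primary, call.is_secondary) == \
            (is_pirna, is_primary, is_secondary)

    def test_pure_function_of_sequence(self):
        """Same sequence, different placement/strand: identical call."""
        seq = "T" + "C" * 8 + "A" + "C" * 20
        a = make_read(chrom="chr1", start=0, end=30, strand="+", seq=seq)
        b = make_read(chrom="chr2", start=5000, end=5030, strand="-", seq=seq)
        assert pk.classify_pirna(a) == pk.classify_pirna(b)


def _toy_annotation():
    iv = pk.GenomicInterval
    ann = AnnotationSet(
        clusters=[iv("chr1", 1000, 2000, ".")],
        repeats=[iv("chr1", 1500, 1600, "+"), iv("chr1", 3000, 3100, "+")],
        genes=[
            GeneModel(
                "g1", iv("chr1", 5000, 6000, "+"),
                exons=(iv("chr1", 5000, 5300, "+"), iv("chr1", 5700, 6000, "+")),
                coding=True,
                cds=(iv("chr1", 5150, 5300, "+"), iv("chr1", 5700, 5850, "+")),
                utr5=(iv("chr1", 5000, 5150, "+"),),
                utr3=(iv("chr1", 5850, 6000, "+"),),
            ),
            GeneModel(
                "g2", iv("chr1", 8000, 8600, "-"),
                exons=(iv("chr1", 8000, 8200, "-"), iv("chr1", 8400, 8600, "-")),
                coding=False,
            ),
        ],
    )
    return ann


@pytest.fixture(scope="module")
def index():
    return pk.AnnotationIndex(_toy_annotation())


class TestAnnotateRead:
    def test_cluster_beats_repeat(self, index):
        read = make_read(start=1550, end=1580)
        assert pk.annotate_read(read, index).category == "piRNA_cluster"

    def test_no_overlap_is_intergenic(self, index):
        read = make_read(start=20000, end=20030)
        assert pk.annotate_read(read, index).category == "intergenic"

    def test_antisense_coding_exon(self, index):
        read = make_read(start=5160, end=5190, strand="-")
        call = pk.annotate_read(read, index)
        assert call.category == "exon_coding"
        assert call.antisense
        assert call.mrna_subtype == "CDS"

    def test_one_bp_overlap_counts(self, index):
        read = make_read(start=3099, end=3129, strand="+")
        assert pk.annotate_read(read, index).category == "repeat"
        read2 = make_read(start=3100, end=3130, strand="+")
        assert pk.annotate_read(read2, index).category == "intergenic"

    def test_intron_and_noncoding(self, index):
        assert pk.annotate_read(make_read(start=5400, end=5430),
                                index).category == "intron"
        assert pk.annotate_read(make_read(start=8050, end=8080, strand="-"),
                                index).category == "exon_noncoding"

    def test_cluster_reads_get_secondary_annotation(self, index):
        in_repeat = make_read(start=1550, end=1580)
        call = pk.annotate_read(in_repeat, index)
        assert call.category == "piRNA_cluster"
        assert call.secondary_category == "repeat"
        plain = make_read(start=1100, end=1130)
        assert pk.annotate_read(plain, index).secondary_category == "intergenic"

    def test_utr_subtypes(self, index):
        assert pk.annotate_read(make_read(start=5050, end=5080, strand="+"),
                                index).mrna_subtype == "5'UTR"
        assert pk.annotate_read(make_read(start=5900, end=5930, strand="+"),
                                index).mrna_subtype == "3'UTR"


def _oracle_category(read, ann):
    """Exhaustive priority-ordered overlap scan (independent of the index)."""
    def hits(ivs):
        return any(read.interval.overlaps(iv) for iv in ivs)

    layers = {
        "piRNA_cluster": ann.clusters,
        "repeat": ann.repeats,
        "exon_coding": [iv for g in ann.genes if g.coding for iv in g.exons],
        "exon_noncoding": [iv for g in ann.genes if not g.coding
                           for iv in g.exons],
        "intron": [iv for g in ann.genes for iv in g.introns],
    }
    for layer in PRIORITY:
        if hits(layers[layer]):
            return layer
    return "intergenic"


class TestAnnotationOracle:
    def test_matches_exhaustive_scan_on_random_sets(self):
        """Priority assignment agrees with brute force on random features."""
        rng = np.random.default_rng(123)
        iv = pk.GenomicInterval
        for trial in range(20):
            ann = AnnotationSet()
            for _ in range(rng.integers(1, 40)):
                s = int(rng.integers(0, 50_000))
                ann.clusters.append(iv("chr1", s, s + int(rng.integers(50, 2000))))
            for _ in range(rng.integers(1, 60)):
                s = int(rng.integers(0, 50_000))
                ann.repeats.append(
                    iv("chr1", s, s + int(rng.integers(20, 400)),
                       "+" if rng.random() < 0.5 else "-"))
            for gi in range(rng.integers(1, 30)):
                s = int(rng.integers(0, 50_000))
                L = int(rng.integers(300, 2000))
                e1 = iv("chr1", s, s + L // 4, "+")
                e2 = iv("chr1", s + L // 2, s + L, "+")
                ann.genes.append(GeneModel(
                    f"t{trial}g{gi}", iv("chr1", s, s + L, "+"),
                    exons=(e1, e2), coding=bool(rng.random() < 0.5)))
            index = pk.AnnotationIndex(ann)
            for _ in range(50):
                start = int(rng.integers(0, 52_000))
                read = make_read(start=start, end=start + 28,
                                 strand="+" if rng.random() < 0.5 else "-")
                assert pk.annotate_read(read, index).category == \
                    _oracle_category(read, ann)


class TestPartitionAndSummaries:
    def test_partition_counts(self):
        reads = [make_read(start=100 * i, end=100 * i + 28, read_id=f"r{i}")
                 for i in range(10)]
        sample = pk.SampleSet("s", reads=reads)
        hits = [pk.GenomicInterval("chr1", 0, 150)]  # overlaps reads 0 and 1
        subset, pct = pk.partition_by_intervals(sample, hits, "clip")
        assert len(subset) == 2
        assert pct == 20.0
        whole = [pk.GenomicInterval("chr1", 0, 10_000)]
        _, pct_all = pk.partition_by_intervals(sample, whole, "all")
        assert pct_all == 100.0
        _, pct_none = pk.partition_by_intervals(sample, [], "none")
        assert pct_none == 0.0

    def test_category_percentages_sum_to_100(self, wt_sample, toy_world):
        _, ann = toy_world
        sample, truth = wt_sample
        index = pk.AnnotationIndex(ann)
        calls = pk.classify_and_annotate(sample, index)
        summary = pk.summarize_categories(calls)
        cat = summary[summary["metric"] == "category"]
        assert abs(cat["percent"].sum() - 100.0) < 1e-9
        # generator cross-check: annotation recovers planted categories
        merged = calls.merge(truth.table[["read_id", "category"]],
                             on="read_id", suffixes=("", "_truth"))
        assert (merged["category"] == merged["category_truth"]).all()

    def test_exclusivity_single_category_per_read(self, wt_sample, toy_world):
        _, ann = toy_world
        sample, _ = wt_sample
        calls = pk.classify_and_annotate(sample, pk.AnnotationIndex(ann))
        assert calls["category"].isin(list(PRIORITY) + ["intergenic"]).all()
        assert len(calls) == len(sample)

    def test_simple_counting_example(self):
        import pandas as pd
        calls = pd.DataFrame(dict(
            read_id=list("abcd"),
            category=["piRNA_cluster", "piRNA_cluster", "repeat", "intergenic"],
            is_pirna=[True] * 4,
        ))
        summary = pk.summarize_categories(calls)
        by = summary.set_index("name")
        cat = summary[summary["metric"] == "category"].set_index("name")
        assert cat.loc["piRNA_cluster", "percent"] == 50.0
        assert cat.loc["repeat", "percent"] == 25.0
        assert cat.loc["intergenic", "percent"] == 25.0
        assert by.loc["meets_pirna_criteria", "percent"] == 100.0
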