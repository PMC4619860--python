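"""Overlap-end truncation assignment and the Welch end comparison."""

import numpy as np
import pytest
from scipy import stats

import pirnakit as pk
from pirnakit.truncation import welch_ttest

from conftest import make_read


class TestBuildPools:
    def test_boundary_partition(self):
        r27 = make_read(start=100, end=127, read_id="s")
        r28 = make_read(start=300, end=328, read_id="l")
        sample = pk.SampleSet("x", reads=[r27, r28])
        long_pool, short_pool = pk.build_pools(sample)
        assert [r.read_id for r in long_pool] == ["l"]
        assert [r.read_id for r in short_pool] == ["s"]

    def test_single_sample_mode_draws_both_pools(self):
        reads = [make_read(start=100, end=126, read_id="s"),
                 make_read(start=300, end=330, read_id="l")]
        sample = pk.SampleSet("x", reads=reads)
        lp, sp = pk.build_pools(sample)
        assert len(lp) == 1 and len(sp) == 1

    def test_long_pool_dedup_by_start_length(self):
        a = make_read(start=100, end=130, read_id="a")
        b = make_read(start=100, end=130, read_id="b")
        short = make_read(start=500, end=525, read_id="s")
        lp, _ = pk.build_pools(pk.SampleSet("x", reads=[a, b, short]))
        assert len(lp) == 1

    def test_denest_long_pool(self):
        outer = make_read(start=100, end=132, read_id="outer")
        inner = make_read(start=102, end=130, read_id="inner")
        short = make_read(start=500, end=525, read_id="s")
        sample = pk.SampleSet("x", reads=[outer, inner, short])
        lp, _ = pk.build_pools(sample, denest_long=True)
        assert [r.read_id for r in lp] == ["outer"]

    def test_empty_pool_is_an_error(self):
        only_short = pk.SampleSet("x", reads=[make_read(start=0, end=25)])
        with pytest.raises(ValueError, match="long pool"):
            pk.build_pools(only_short)


class TestAssignAndProfile:
    def test_plus_strand_sign_convention(self):
        L = make_read(start=100, end=130, read_id="L")
        S = make_read(start=100, end=127, read_id="S")
        prof = pk.assign_and_profile([S], [L])
        assert (prof.pairs[0].delta5, prof.pairs[0].delta3) == (0, -3)

    def test_minus_strand_sign_convention(self):
        L = make_read(start=100, end=130, strand="-", read_id="L")
        S = make_read(start=103, end=130, strand="-", read_id="S")
        prof = pk.assign_and_profile([S], [L])
        assert (prof.pairs[0].delta5, prof.pairs[0].delta3) == (0, -3)

    def test_not_contained_is_unassigned(self):
        L = make_read(start=100, end=130, read_id="L")
        S = make_read(start=95, end=120, read_id="S")
        prof = pk.assign_and_profile([S], [L])
        assert prof.n_unassigned == 1 and not prof.pairs

    def test_non_contained_mode_permits_positive_deltas(self):
        L = make_read(start=100, end=130, read_id="L")
        S = make_read(start=95, end=120, read_id="S")
        prof = pk.assign_and_profile([S], [L], contain=False)
        assert prof.pairs[0].delta5 == 5      # short 5'-extends past long
        assert prof.pairs[0].delta3 == -10

    def test_longest_container_wins(self):
        long_a = make_read(start=100, end=130, read_id="len30")
        long_b = make_read(start=98, end=130, read_id="len32")
        S = make_read(start=104, end=129, read_id="S")
        prof = pk.assign_and_profile([S], [long_a, long_b])
        assert len(prof.pairs) == 1
        assert prof.pairs[0].long.read_id == "len32"

    def test_all_containing_records_every_partner(self):
        long_a = make_read(start=100, end=130, read_id="a")
        long_b = make_read(start=98, end=130, read_id="b")
        S = make_read(start=104, end=129, read_id="S")
        prof = pk.assign_and_profile([S], [long_a, long_b],
                                     all_containing=True)
        assert len(prof.pairs) == 2
        assert prof.n_assigned == 1  # one short read assigned

    def test_contained_mode_never_positive_and_counts_reconcile(self, toy_world):
        genome, ann = toy_world
        cfg = pk.SyntheticConfig(seed=40, n_reads=600, tile_loci=True,
                                 length_mixture=((32, 1.0, 1e-6),))
        long_s, _ = pk.simulate_reads(cfg, genome, ann)
        short_s, _ = pk.derive_truncated(long_s, {1: 0.5, 4: 0.5}, seed=2)
        spec = pk.BinningSpec(long_pool=(32, 32), short_pool=(27, 31))
        lp, sp = pk.build_pools(long_s, short_s, spec)
        prof = pk.assign_and_profile(sp, lp, spec=spec)
        assert (prof.delta5 <= 0).all() and (prof.delta3 <= 0).all()
        assert prof.n_assigned + prof.n_unassigned == len(sp)

    def test_matches_exhaustive_all_pairs_search(self):
        """Tree-based assignment equals brute-force containment scan."""
        rng = np.random.default_rng(7)
        longs, shorts = [], []
        for i in range(150):
            s = int(rng.integers(0, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            longs.append(make_read(start=s, end=s + int(rng.integers(28, 33)),
                                   strand=strand, read_id=f"L{i}"))
        for i in range(150):
            s = int(rng.integers(0, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            shorts.append(make_read(start=s, end=s + int(rng.integers(23, 28)),
                                    strand=strand, read_id=f"S{i}"))
        prof = pk.assign_and_profile(shorts, longs)
        got = {(p.short.read_id, p.long.read_id) for p in prof.pairs}
        expected = set()
        for s in shorts:
            containers = [
                l for l in longs
                if l.strand == s.strand
                and l.interval.chrom == s.interval.chrom
                and l.interval.start <= s.interval.start
                and s.interval.end <= l.interval.end
                and l.interval.length > s.interval.length
            ]
            if containers:
                best = min(containers,
                           key=lambda l: (-l.interval.length,
                                          l.interval.start,
                                          longs.index(l)))
                expected.add((s.read_id, best.read_id))
        assert got == expected

    def test_flag_conflict(self):
        with pytest.raises(ValueError):
            pk.assign_and_profile([], [], contain=False, all_containing=True)


class TestWelch:
    def test_hand_computed_example(self):
        """A={3,3,3,4,4}, B={1,1,2,2,2}: t = 1.8/sqrt(0.12), df = 8."""
        res = welch_ttest([3, 3, 3, 4, 4], [1, 1, 2, 2, 2])
        assert np.isclose(res.t, 1.8 / np.sqrt(0.12))
        assert np.isclose(res.t, 5.196, atol=1e-3)
        assert np.isclose(res.df, 8.0)

    def test_matches_scipy_reference(self):
        """Independent oracle: scipy's Welch t, df, p and CI to 1e-9."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(2.0, 1.5, size=rng.integers(5, 60))
            b = rng.normal(1.2, 0.8, size=rng.integers(5, 60))
            ours = welch_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            ci = ref.confidence_interval(0.95)
            assert np.isclose(ours.t, ref.statistic, rtol=1e-9)
            assert np.isclose(ours.df, ref.df, rtol=1e-9)
            assert np.isclose(ours.p, ref.pvalue, rtol=1e-9, atol=1e-300)
            assert np.isclose(ours.ci_low, ci.low, rtol=1e-9)
            assert np.isclose(ours.ci_high, ci.high, rtol=1e-9)

    def test_identical_distributions_null(self):
        res = welch_ttest([2, 2, 2], [2, 2, 2])
        assert res.t == 0.0 and res.p == 1.0


class TestCompareGenotypes:
    def test_self_comparison_is_null(self, toy_world):
        genome, ann = toy_world
        cfg = pk.SyntheticConfig(seed=41, n_reads=500, tile_loci=True,
                                 length_mixture=((32, 1.0, 1e-6),))
        long_s, _ = pk.simulate_reads(cfg, genome, ann)
        short_s, _ = pk.derive_truncated(long_s, {1: 0.4, 2: 0.6}, seed=3)
        spec = pk.BinningSpec(long_pool=(32, 32), short_pool=(27, 31))
        lp, sp = pk.build_pools(long_s, short_s, spec)
        prof = pk.assign_and_profile(sp, lp, spec=spec)
        out = pk.compare_genotypes(prof, prof)
        assert out["end3"].mean_diff == 0.0
        assert out["end3"].ci_low <= 0.0 <= out["end3"].ci_high
        assert (out["proportions"]["proportion_diff"] == 0.0).all()

    def test_deeper_mutant_truncation_detected(self, toy_world):
        genome, ann = toy_world
        cfg = pk.SyntheticConfig(seed=42, n_reads=1200, tile_loci=True,
                                 length_mixture=((32, 1.0, 1e-6),))
        long_s, _ = pk.simulate_reads(cfg, genome, ann)
        shallow, _ = pk.derive_truncated(long_s, {1: 0.8, 2: 0.2}, seed=4,
                                         sample_id="wt_like")
        deep, _ = pk.derive_truncated(long_s, {3: 0.3, 4: 0.4, 5: 0.3},
                                      seed=5, sample_id="mut_like")
        spec = pk.BinningSpec(long_pool=(32, 32), short_pool=(27, 31))
        profiles = []
        for short in (shallow, deep):
            lp, sp = pk.build_pools(long_s, short, spec)
            profiles.append(pk.assign_and_profile(sp, lp, spec=spec))
        out = pk.compare_genotypes(profiles[0], profiles[1])
        assert out["end3"].mean_diff > 0
        assert out["end3"].ci_low > 0  # CI excludes zero
        props = out["proportions"]
        small = props[(props["end"] == "3") & (props["delta"] >= -2)]
        large = props[(props["end"] == "3") & (props["delta"] <= -3)]
        assert (small["proportion_diff"] <= 0).all()   # WT-enriched small
        assert (large["proportion_diff"] >= 0).all()   # mutant-enriched large

    def test_spec_mismatch(self, toy_world):
        genome, ann = toy_world
        cfg = pk.SyntheticConfig(seed=43, n_reads=200, tile_loci=True,
                                 length_mixture=((32, 1.0, 1e-6),))
        long_s, _ = pk.simulate_reads(cfg, genome, ann)
        short_s, _ = pk.derive_truncated(long_s, {1: 1.0}, seed=6)
        spec_a = pk.BinningSpec(long_pool=(32, 32), short_pool=(27, 31))
        spec_b = pk.BinningSpec(long_pool=(32, 32), short_pool=(26, 31))
        lp, sp = pk.build_pools(long_s, short_s, spec_a)
        pa = pk.assign_and_profile(sp, lp, spec=spec_a)
        pb = pk.assign_and_profile(sp, lp, spec=spec_b)
        with pytest.raises(ValueError, match="spec"):
            pk.compare_genotypes(pa, pb)
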