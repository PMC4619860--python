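import pytest

import pirnakit as pk


@pytest.fixture(scope="session")
def toy_world():
    """Shared small genome + annotation (deterministic, seed 0)."""
    cfg = pk.wildtype_config(seed=0, n_reads=10)
    genome, ann = pk.simulate_genome(cfg)
    return genome, ann


@pytest.fixture(scope="session")
def wt_sample(toy_world):
    genome, ann = toy_world
    cfg = pk.wildtype_config(seed=11, n_reads=3000)
    return pk.simulate_reads(cfg, genome, ann)


@pytest.fixture(scope="session")
def mut_sample(toy_world):
    genome, ann = toy_world
    cfg = pk.mutant_config(seed=12, n_reads=3000)
    return pk.simulate_reads(cfg, genome, ann)


def make_read(chrom="chr1", start=100, end=130, strand="+", seq=None,
              ref=None, read_id="r", mapq=60, n_hits=1):
    """Hand-built read; sequence defaults to all-C of the right length."""
    n = end - start
    seq = seq if seq is not None else "C" * n
    return pk.AlignedRead(
        read_id=read_id, seq=seq,
        interval=pk.GenomicInterval(chrom, start, end, strand),
        strand=strand, mapq=mapq, n_hits=n_hits, ref_bases=ref,
    )
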