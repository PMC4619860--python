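"""End-to-end orchestration: configuration, staging, and tabular reporting.

``run_pipeline`` executes the analysis stages in dependency order over a
wild-type/mutant pair of libraries — either simulated in-process or loaded
from SAM/BAM — and writes one TSV per stage plus a JSON summary. Every
table is stamped with the configuration hash and tool version on a leading
comment line, and per-stage read tallies are logged so no stage drops
reads silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotate import AnnotationIndex, classify_and_annotate, summarize_categories
from .binning import BinMatrix, BinningSpec, bin_expression, differential_bins
from .core import FilterPolicy, load_alignments, write_sam
from .endlength import end_modification, end_modification_table, length_distribution
from .features import read_gff3, write_gff3
from .pingpong import StringentPairCriteria, five_prime_overlaps, pingpong_z, \
    stringent_pairs
from .simulate import mutant_config, simulate_genome, simulate_reads, \
    wildtype_config, write_fasta, write_ground_truth
from .truncation import assign_and_profile, build_pools, compare_ends

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    With ``simulate=True`` (default) a synthetic wild-type/mutant pair is
    generated under ``seed``; otherwise ``alignments_wt``/``alignments_mut``,
    ``reference`` and ``annotation`` name the inputs on disk.
    """

    outdir: str = "pirnakit_out"
    seed: int = 0
    simulate: bool = True
    n_reads: int = 10_000
    alignments_wt: Optional[str] = None
    alignments_mut: Optional[str] = None
    reference: Optional[str] = None
    annotation: Optional[str] = None
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    spec: BinningSpec = field(default_factory=BinningSpec)
    denest: bool = False
    contain: bool = True
    all_containing: bool = False
    pingpong_focal: int = 10
    pingpong_window: tuple[int, int] = (1, 20)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("alignments_wt", "alignments_mut", "reference",
                         "annotation"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"config: {name} required when not simulating")
                if not Path(value).exists():
                    raise FileNotFoundError(f"config: {name} missing: {value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pirnakit {__version__} config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a wild-type/mutant pair; return the result bundle.

    Stages: simulate (optional), classify+annotate, length distributions,
    3'-end modification, binned expression per sample, differential bins,
    truncation profiling (WT long pool vs mutant short pool), and ping-pong
    signatures. Deterministic under a fixed seed and config.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict(),
                    "config_hash": config.config_hash,
                    "version": __version__}

    if config.simulate:
        logger.info("stage simulate: seed=%d n_reads=%d", config.seed,
                    config.n_reads)
        wt_cfg = wildtype_config(seed=config.seed, n_reads=config.n_reads)
        mut_cfg = mutant_config(seed=config.seed + 1, n_reads=config.n_reads)
        genome, annotation = simulate_genome(wt_cfg)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        wt, wt_truth = simulate_reads(wt_cfg, genome, annotation)
        mut, mut_truth = simulate_reads(mut_cfg, genome, annotation)
        write_fasta(genome, outdir / "genome.fa")
        write_gff3(annotation, outdir / "annotation.gff3")
        write_sam(wt, outdir / "wt.sam", chrom_sizes)
        write_sam(mut, outdir / "mut.sam", chrom_sizes)
        write_ground_truth(wt_truth, outdir / "wt_truth.tsv")
        write_ground_truth(mut_truth, outdir / "mut_truth.tsv")
    else:
        annotation = read_gff3(config.annotation)
        import pyfaidx

        fa = pyfaidx.Fasta(config.reference)
        chrom_sizes = {name: len(fa[name]) for name in fa.keys()}
        wt = load_alignments(config.alignments_wt, config.policy,
                             reference=config.reference, condition="wild_type")
        mut = load_alignments(config.alignments_mut, config.policy,
                              reference=config.reference, condition="mutant")
    for s in (wt, mut):
        s.require_nonempty("pipeline")
        logger.info("stage load: %s retained %d reads (tally=%s)",
                    s.sample_id, len(s), dict(s.filter_tally))

    index = AnnotationIndex(annotation)
    samples = {"wt": wt, "mut": mut}
    summaries = {}
    for label, sample in samples.items():
        calls = classify_and_annotate(sample, index, config.policy)
        _write_table(calls, outdir / f"{label}_calls.tsv", config)
        summary = summarize_categories(calls)
        _write_table(summary, outdir / f"{label}_category_summary.tsv", config)
        summaries[label] = summary
        logger.info("stage classify: %s -> %d calls", label, len(calls))
    bundle["category_summaries"] = summaries

    lengths = pd.concat(
        [length_distribution(s, config.policy) for s in samples.values()],
        ignore_index=True,
    )
    _write_table(lengths, outdir / "length_distribution.tsv", config)
    bundle["length_distribution"] = lengths

    mods = [end_modification(s, config.policy) for s in samples.values()]
    mod_table = end_modification_table(mods)
    _write_table(mod_table, outdir / "end_modification.tsv", config)
    bundle["end_modification"] = mod_table

    spec = dataclasses.replace(config.spec, denest=config.denest)
    matrices: dict[str, BinMatrix] = {}
    for label, sample in samples.items():
        m = bin_expression(sample, spec, chrom_sizes, policy=config.policy)
        matrices[label] = m
        _write_table(m.to_frame(), outdir / f"{label}_bins.tsv", config)
        _write_table(m.bin_summary(), outdir / f"{label}_bin_summary.tsv",
                     config)
        logger.info("stage bins: %s in_range=%d out_of_range=%d", label,
                    m.n_in_range, m.n_out_of_range)
    diff = differential_bins(matrices["wt"], matrices["mut"])
    _write_table(diff.to_frame(), outdir / "diff_bins.tsv", config)
    bundle["diff_bins"] = diff

    long_pool, short_pool = build_pools(
        wt, mut, spec, denest_long=config.denest, policy=config.policy)
    profile = assign_and_profile(
        short_pool, long_pool, contain=config.contain,
        all_containing=config.all_containing, sample_long=wt.sample_id,
        sample_short=mut.sample_id, spec=spec)
    _write_table(profile.to_frame(), outdir / "truncation_pairs.tsv", config)
    hist = pd.concat([profile.histogram("5"), profile.histogram("3")],
                     ignore_index=True)
    _write_table(hist, outdir / "truncation_histogram.tsv", config)
    welch = compare_ends(profile)
    bundle["truncation"] = {"profile": profile, "welch": welch}
    logger.info("stage trunc: %d pairs, unassigned=%d", len(profile.pairs),
                profile.n_unassigned)

    window = tuple(range(config.pingpong_window[0],
                         config.pingpong_window[1] + 1))
    pp = {}
    for label, sample in samples.items():
        h = five_prime_overlaps(sample, o_max=config.pingpong_window[1],
                                policy=config.policy)
        result = pingpong_z(h, focal=config.pingpong_focal, window=window)
        _write_table(h.to_frame(), outdir / f"{label}_overlap_histogram.tsv",
                     config)
        pairs, pair_stats = stringent_pairs(sample, index,
                                            StringentPairCriteria(),
                                            config.policy)
        pp[label] = {"z": result, "stringent": pair_stats}
        logger.info("stage pingpong: %s z=%.2f stringent_pairs=%d", label,
                    result.z, pair_stats["n_pairs"])
    bundle["pingpong"] = pp

    summary = {
        "config_hash": config.config_hash,
        "version": __version__,
        "samples": {k: len(v) for k, v in samples.items()},
        "welch_3p_vs_5p": dataclasses.asdict(welch),
        "pingpong_z": {k: v["z"].z for k, v in pp.items()},
        "stringent_pairs": {k: v["stringent"] for k, v in pp.items()},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    bundle["summary"] = summary
    return bundle
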