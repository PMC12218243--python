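"""End-to-end orchestration: trim -> split -> prep -> denoise -> correct/merge.

This is the in-memory engine behind the CLI; each stage is importable on its
own for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from ssumix.amplicon_io import PrimerPair, ReadPair, trim_primers
from ssumix.correction_merge import (
    CorrectedASVTable,
    RunChemistry,
    merge_tables,
)
from ssumix.denoiser import DenoiseStats, RawASVTable, denoise_samples
from ssumix.domain_splitter import Pool, SplitIndex, split_reads
from ssumix.read_prep import PrepReport, prepare_pool


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    # primer trimming
    primer_max_mismatch: int = 2
    primer_slack: int = 5
    # splitting
    split_k: int = 31
    min_votes: int = 5
    min_margin: float = 2.0
    # read prep
    max_ee: float = 2.0
    trunc_fwd: int = 220
    trunc_rev: int = 180
    spacer_len: int = 10
    min_overlap: int = 20
    max_mismatch_frac: float = 0.10
    # denoising
    alpha: float = 2.0
    max_dist: int = 10
    bimera_min_fold: float = 2.0
    # merging
    min_depth: int = 5000
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


@dataclass
class PipelineResult:
    corrected: CorrectedASVTable
    table_16S: RawASVTable
    table_18S: RawASVTable
    stats: dict[tuple[str, Pool], DenoiseStats]
    prep_reports: list[PrepReport]
    split_counts: dict[str, tuple[int, int, int]]  # sample -> (n16, n18, nun)
    chemistry: dict[str, RunChemistry]
    n_trimmed: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    reads_by_sample: Mapping[str, list[ReadPair]],
    index: SplitIndex,
    primers: PrimerPair,
    sample_runs: Mapping[str, str],
    conc_by_run: Mapping[str, tuple[float | None, float | None]],
    borrowed: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage over demultiplexed, per-sample read pairs.

    ``conc_by_run`` supplies the bioanalyzer concentrations; the post-split
    read totals that complete each run's chemistry are computed here from the
    split step itself. Runs listed in ``borrowed`` take their correction
    factors from the named source run instead.
    """
    cfg = config or PipelineConfig()
    borrowed = borrowed or {}

    pool16: dict[str, list[ReadPair]] = {}
    pool18: dict[str, list[ReadPair]] = {}
    split_counts: dict[str, tuple[int, int, int]] = {}
    n_trimmed: dict[str, int] = {}
    for sample_id, pairs in reads_by_sample.items():
        trimmed = [
            t for t in (
                trim_primers(p, primers, cfg.primer_max_mismatch, cfg.primer_slack)
                for p in pairs
            )
            if t is not None
        ]
        n_trimmed[sample_id] = len(trimmed)
        p16, p18, unassigned = split_reads(
            trimmed, index, cfg.min_votes, cfg.min_margin
        )
        pool16[sample_id] = p16
        pool18[sample_id] = p18
        split_counts[sample_id] = (len(p16), len(p18), len(unassigned))

    prepared16: dict[str, list] = {}
    prepared18: dict[str, list] = {}
    prep_reports: list[PrepReport] = []
    for sample_id in reads_by_sample:
        prep16, rep16 = prepare_pool(
            pool16[sample_id], Pool.SSU16S, sample_id,
            max_ee=cfg.max_ee, min_overlap=cfg.min_overlap,
            max_mismatch_frac=cfg.max_mismatch_frac,
        )
        prep18, rep18 = prepare_pool(
            pool18[sample_id], Pool.SSU18S, sample_id,
            max_ee=cfg.max_ee, trunc_fwd=cfg.trunc_fwd,
            trunc_rev=cfg.trunc_rev, spacer_len=cfg.spacer_len,
        )
        prepared16[sample_id] = prep16
        prepared18[sample_id] = prep18
        prep_reports.extend([rep16, rep18])

    n_input16 = {s: len(pool16[s]) for s in reads_by_sample}
    n_input18 = {s: len(pool18[s]) for s in reads_by_sample}
    table16, _, stats16 = denoise_samples(
        {s: p for s, p in prepared16.items() if n_input16[s] > 0},
        Pool.SSU16S,
        n_input16,
        alpha=cfg.alpha, max_dist=cfg.max_dist,
        bimera_min_fold=cfg.bimera_min_fold,
    )
    table18, _, stats18 = denoise_samples(
        {s: p for s, p in prepared18.items() if n_input18[s] > 0},
        Pool.SSU18S,
        n_input18,
        alpha=cfg.alpha, max_dist=cfg.max_dist,
        bimera_min_fold=cfg.bimera_min_fold,
    )
    stats: dict[tuple[str, Pool], DenoiseStats] = {}
    for s, st in stats16.items():
        stats[(s, Pool.SSU16S)] = st
    for s, st in stats18.items():
        stats[(s, Pool.SSU18S)] = st

    run_seqs: dict[str, list[int]] = {}
    for sample_id, run_id in sample_runs.items():
        if sample_id not in split_counts:
            continue
        n16, n18, _ = split_counts[sample_id]
        totals = run_seqs.setdefault(run_id, [0, 0])
        totals[0] += n16
        totals[1] += n18
    chemistry: dict[str, RunChemistry] = {}
    for run_id, (n16, n18) in run_seqs.items():
        conc16, conc18 = conc_by_run.get(run_id, (None, None))
        chemistry[run_id] = RunChemistry(
            run_id=run_id,
            conc_16S=conc16,
            conc_18S=conc18,
            seqs_16S=n16,
            seqs_18S=n18,
            borrowed_from=borrowed.get(run_id),
        )

    corrected = merge_tables(
        table16, table18, chemistry, stats, sample_runs, min_depth=cfg.min_depth
    )
    return PipelineResult(
        corrected=corrected,
        table_16S=table16,
        table_18S=table18,
        stats=stats,
        prep_reports=prep_reports,
        split_counts=split_counts,
        chemistry=chemistry,
        n_trimmed=n_trimmed,
    )
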