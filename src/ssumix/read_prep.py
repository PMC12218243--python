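"""Pool-specific read preparation.

16S pairs are overlap-merged (their amplicons are shorter than twice the read
length); 18S pairs do not overlap at 2x250 and are instead truncated to fixed
lengths (220 forward / 180 reverse) and concatenated around an N spacer so
that ASVs are length-comparable across studies. Both pools pass through an
expected-error (MaxEE) filter first.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from ssumix.amplicon_io import ReadPair, revcomp
from ssumix.domain_splitter import Pool


@dataclass(frozen=True)
class PreparedSequence:
    """A single denoiser-ready sequence (merged 16S or concatenated 18S)."""

    sample_id: str
    pool: Pool
    sequence: str
    qual: tuple[int, ...]


@dataclass(frozen=True)
class MaxEEParams:
    max_expected_errors: float = 2.0
    trunc_fwd: int | None = None
    trunc_rev: int | None = None

    def __post_init__(self) -> None:
        if self.max_expected_errors <= 0:
            raise ValueError("max_expected_errors must be > 0")


class FilterResult(Enum):
    PASS = "pass"
    FAIL_MAXEE = "fail_maxee"
    FAIL_TOO_SHORT = "fail_too_short"


_EE_TABLE = tuple(10.0 ** (-q / 10.0) for q in range(61))


def expected_errors(qual: Sequence[int]) -> float:
    """Sum of per-base error probabilities, sum_i 10^(-Q_i/10)."""
    return float(sum(_EE_TABLE[q] if 0 <= q <= 60 else 10.0 ** (-q / 10.0)
                     for q in qual))


def filter_maxee(pair: ReadPair, params: MaxEEParams) -> FilterResult:
    """MaxEE decision for a pair; truncation (if configured) is applied before
    computing expected errors. The boundary EE == max_ee passes — only reads
    with errors strictly higher than the threshold are discarded.
    """
    fq: Sequence[int] = pair.fwd_qual
    rq: Sequence[int] = pair.rev_qual
    if params.trunc_fwd is not None:
        if len(fq) < params.trunc_fwd:
            return FilterResult.FAIL_TOO_SHORT
        fq = fq[: params.trunc_fwd]
    if params.trunc_rev is not None:
        if len(rq) < params.trunc_rev:
            return FilterResult.FAIL_TOO_SHORT
        rq = rq[: params.trunc_rev]
    if expected_errors(fq) > params.max_expected_errors:
        return FilterResult.FAIL_MAXEE
    if expected_errors(rq) > params.max_expected_errors:
        return FilterResult.FAIL_MAXEE
    return FilterResult.PASS


def merge_overlap(
    pair: ReadPair,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
    qual_cap: int = 41,
) -> PreparedSequence | None:
    """Ungapped overlap merge of a 16S pair.

    The reverse mate is reverse-complemented; candidate overlaps of length
    >= min_overlap with mismatch fraction <= max_mismatch_frac compete on
    matching-base count (ties broken toward the longer overlap). Within the
    overlap, agreeing bases get the summed quality capped at ``qual_cap``;
    disagreeing positions take the higher-quality base with quality |q1 - q2|.
    Returns None if no admissible overlap exists.
    """
    fwd = pair.fwd_seq
    fq = pair.fwd_qual
    rev = revcomp(pair.rev_seq)
    rq = pair.rev_qual[::-1]
    f_arr = np.frombuffer(fwd.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(rev.encode(), dtype=np.uint8)
    best: tuple[int, int] | None = None  # (matches, overlap_len)
    max_len = min(len(fwd), len(rev))
    for olen in range(min_overlap, max_len + 1):
        matches = int((f_arr[len(fwd) - olen :] == r_arr[:olen]).sum())
        if (olen - matches) / olen > max_mismatch_frac:
            continue
        if best is None or (matches, olen) >= best:
            best = (matches, olen)
    if best is None:
        return None
    _, olen = best
    f_start = len(fwd) - olen
    seq_parts: list[str] = [fwd[:f_start]]
    qual_parts: list[int] = list(fq[:f_start])
    for i in range(olen):
        fb, fqv = fwd[f_start + i], fq[f_start + i]
        rb, rqv = rev[i], rq[i]
        if fb == rb:
            seq_parts.append(fb)
            qual_parts.append(min(fqv + rqv, qual_cap))
        elif fqv >= rqv:
            seq_parts.append(fb)
            qual_parts.append(abs(fqv - rqv))
        else:
            seq_parts.append(rb)
            qual_parts.append(abs(fqv - rqv))
    seq_parts.append(rev[olen:])
    qual_parts.extend(rq[olen:])
    return PreparedSequence(
        sample_id=pair.sample_id,
        pool=Pool.SSU16S,
        sequence="".join(seq_parts),
        qual=tuple(qual_parts),
    )


def concat_18S(
    pair: ReadPair,
    trunc_fwd: int = 220,
    trunc_rev: int = 180,
    spacer_len: int = 10,
) -> PreparedSequence | None:
    """Fixed-length truncate and concatenate a non-overlapping 18S pair.

    Output = fwd[:trunc_fwd] + N*spacer_len + revcomp(rev[:trunc_rev]), with
    Q0 qualities over the spacer. Pairs with a mate shorter than its
    truncation length are rejected (None) so every 18S output in a study has
    identical length.
    """
    if len(pair.fwd_seq) < trunc_fwd or len(pair.rev_seq) < trunc_rev:
        return None
    fwd = pair.fwd_seq[:trunc_fwd]
    fq = pair.fwd_qual[:trunc_fwd]
    rev = revcomp(pair.rev_seq[:trunc_rev])
    rq = pair.rev_qual[:trunc_rev][::-1]
    return PreparedSequence(
        sample_id=pair.sample_id,
        pool=Pool.SSU18S,
        sequence=fwd + "N" * spacer_len + rev,
        qual=fq + (0,) * spacer_len + rq,
    )


@dataclass
class PrepReport:
    """Per-sample, per-pool read accounting through preparation."""

    sample_id: str
    pool: Pool
    n_input: int = 0
    n_maxee_fail: int = 0
    n_too_short: int = 0
    n_merge_fail: int = 0
    n_output: int = 0


def prepare_pool(
    pairs: list[ReadPair],
    pool: Pool,
    sample_id: str,
    max_ee: float = 2.0,
    trunc_fwd: int = 220,
    trunc_rev: int = 180,
    spacer_len: int = 10,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
) -> tuple[list[PreparedSequence], PrepReport]:
    """Run the pool-appropriate preparation over one sample's split reads."""
    report = PrepReport(sample_id=sample_id, pool=pool, n_input=len(pairs))
    if pool is Pool.SSU18S:
        params = MaxEEParams(max_ee, trunc_fwd, trunc_rev)
    else:
        params = MaxEEParams(max_ee)
    out: list[PreparedSequence] = []
    for pair in pairs:
        verdict = filter_maxee(pair, params)
        if verdict is FilterResult.FAIL_TOO_SHORT:
            report.n_too_short += 1
            continue
        if verdict is FilterResult.FAIL_MAXEE:
            report.n_maxee_fail += 1
            continue
        if pool is Pool.SSU16S:
            prepared = merge_overlap(pair, min_overlap, max_mismatch_frac)
            if prepared is None:
                report.n_merge_fail += 1
                continue
        else:
            prepared = concat_18S(pair, trunc_fwd, trunc_rev, spacer_len)
            if prepared is None:
                report.n_too_short += 1
                continue
        out.append(
            PreparedSequence(sample_id, pool, prepared.sequence, prepared.qual)
        )
    report.n_output = len(out)
    return out, report
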