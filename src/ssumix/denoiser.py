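"""Collapse prepared sequences into ASVs, remove bimeras, and account reads.

The denoiser is a deterministic greedy abundance-skew algorithm: unique
sequences are visited in decreasing-abundance order and absorbed into the most
abundant already-accepted center within ``max_dist`` Hamming distance whose
abundance dominates them by the skew rule abundance(u) <= abundance(c) /
2^(alpha*d + 1). Sequences of unequal length never merge.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ssumix.domain_splitter import Pool
from ssumix.errors import UsageError
from ssumix.read_prep import PreparedSequence


def asv_id(sequence: str) -> str:
    """Content-hash feature id: MD5 hex digest of the uppercase sequence."""
    return hashlib.md5(sequence.upper().encode()).hexdigest()


@dataclass
class DenoiseStats:
    """Per-sample, per-pool read accounting through denoising.

    ``n_input`` is fixed at pool entry (post-split, pre-MaxEE) so the pass
    ratio absorbs quality-filter loss as well as chimera loss.
    """

    sample_id: str
    pool: Pool
    n_input: int
    n_filtered: int
    n_denoised: int
    n_nonchimeric: int

    def __post_init__(self) -> None:
        if not (
            self.n_input >= self.n_filtered >= self.n_denoised
            >= self.n_nonchimeric >= 0
        ):
            raise UsageError(
                f"{self.sample_id}/{self.pool.value}: read counts must be "
                "non-increasing through the pipeline"
            )

    @property
    def pass_ratio(self) -> float:
        return compute_pass_ratio(self)


def compute_pass_ratio(stats: DenoiseStats) -> float:
    """Non-chimeric reads divided by reads that entered the pool."""
    if stats.n_input == 0:
        raise UsageError(
            f"{stats.sample_id}/{stats.pool.value}: no input reads; "
            "sample unusable for this pool"
        )
    return stats.n_nonchimeric / stats.n_input


@dataclass
class RawASVTable:
    """Sparse per-pool ASV table: (sample_id, asv_id) -> integer count."""

    pool: Pool
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)  # asv_id -> sequence

    def add(self, sample_id: str, sequence: str, count: int) -> None:
        aid = asv_id(sequence)
        self.sequences[aid] = sequence
        key = (sample_id, aid)
        self.counts[key] = self.counts.get(key, 0) + count

    def sample_depth(self, sample_id: str) -> int:
        return sum(c for (s, _), c in self.counts.items() if s == sample_id)

    def asv_total(self, aid: str) -> int:
        return sum(c for (_, a), c in self.counts.items() if a == aid)

    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self.counts})

    def to_frame(self) -> pd.DataFrame:
        """Dense features-x-samples DataFrame (deterministic ordering)."""
        samples = self.sample_ids()
        asvs = sorted(self.sequences)
        df = pd.DataFrame(0, index=asvs, columns=samples, dtype=int)
        for (s, a), c in self.counts.items():
            df.at[a, s] = c
        return df


def dereplicate(prepared: Iterable[PreparedSequence]) -> list[tuple[str, int]]:
    """Collapse identical sequences; sorted by abundance desc, ties by
    sequence lexicographic order (deterministic)."""
    counts = Counter(p.sequence for p in prepared)
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def _hamming_matrix(query: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return (centers != query).sum(axis=1)


def denoise_greedy(
    derep: list[tuple[str, int]],
    alpha: float = 2.0,
    max_dist: int = 10,
) -> dict[str, str]:
    """Map each unique sequence to its center ASV sequence.

    ``derep`` must already be sorted by (-abundance, sequence). Centers are
    stored per sequence length; a candidate joins the most abundant admissible
    center, else becomes a new center itself.
    """
    mapping: dict[str, str] = {}
    # per length: parallel lists of center sequences and *accumulated*
    # abundances (center + everything absorbed so far), plus uint8 rows for
    # vectorized Hamming distances
    by_len: dict[int, dict] = {}
    for seq, abundance in derep:
        n = len(seq)
        group = by_len.get(n)
        target_idx: int | None = None
        if group is not None:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            dists = _hamming_matrix(arr, np.asarray(group["matrix"]))
            # most abundant admissible center wins; ties -> earliest accepted
            for idx in np.flatnonzero(dists <= max_dist):
                d = int(dists[idx])
                if abundance <= group["abund"][idx] / 2.0 ** (alpha * d + 1):
                    if target_idx is None or (
                        group["abund"][idx] > group["abund"][target_idx]
                    ):
                        target_idx = int(idx)
        if target_idx is not None:
            mapping[seq] = group["seqs"][target_idx]
            group["abund"][target_idx] += abundance
        else:
            mapping[seq] = seq
            if group is None:
                group = {"seqs": [], "abund": [], "matrix": []}
                by_len[n] = group
            group["seqs"].append(seq)
            group["abund"].append(abundance)
            group["matrix"].append(np.frombuffer(seq.encode(), dtype=np.uint8))
    return mapping


def is_bimera_of(child: str, parent_a: str, parent_b: str) -> bool:
    """True iff the child equals a prefix of A joined to a suffix of B at some
    internal breakpoint (exact segment match)."""
    n = len(child)
    for brk in range(1, n):
        if len(parent_a) < brk or len(parent_b) < n - brk:
            continue
        if child[:brk] == parent_a[:brk] and child[brk:] == parent_b[len(parent_b) - (n - brk):]:
            return True
    return False


def remove_bimeras(table: RawASVTable, min_fold: float = 2.0) -> tuple[RawASVTable, list[str]]:
    """Flag and drop ASVs explainable as two-parent chimeras.

    A child is flagged iff two parents exist, each with study-wide abundance
    >= min_fold x the child's, whose prefix+suffix reconstruct the child
    exactly at some breakpoint. Flags are decided against the input table
    (non-iterative), then removed together.
    """
    totals = {aid: table.asv_total(aid) for aid in table.sequences}
    flagged: list[str] = []
    aids = sorted(table.sequences)
    for child in aids:
        child_seq = table.sequences[child]
        child_total = totals[child]
        parents = [
            a for a in aids
            if a != child and totals[a] >= min_fold * child_total
        ]
        found = False
        for pa in parents:
            for pb in parents:
                if is_bimera_of(child_seq, table.sequences[pa], table.sequences[pb]):
                    found = True
                    break
            if found:
                break
        if found:
            flagged.append(child)
    dropped = set(flagged)
    cleaned = RawASVTable(
        pool=table.pool,
        counts={k: c for k, c in table.counts.items() if k[1] not in dropped},
        sequences={a: s for a, s in table.sequences.items() if a not in dropped},
    )
    return cleaned, flagged


def denoise_samples(
    prepared_by_sample: Mapping[str, list[PreparedSequence]],
    pool: Pool,
    n_input_by_sample: Mapping[str, int],
    n_filtered_by_sample: Mapping[str, int] | None = None,
    alpha: float = 2.0,
    max_dist: int = 10,
    bimera_min_fold: float = 2.0,
) -> tuple[RawASVTable, list[str], dict[str, DenoiseStats]]:
    """Denoise every sample of one pool and assemble the raw ASV table.

    Returns (table after bimera removal, flagged asv_ids, stats per sample).
    """
    table = RawASVTable(pool=pool)
    denoised_counts: dict[str, int] = {}
    for sample_id, prepared in prepared_by_sample.items():
        derep = dereplicate(prepared)
        mapping = denoise_greedy(derep, alpha=alpha, max_dist=max_dist)
        per_center: Counter[str] = Counter()
        for seq, abundance in derep:
            per_center[mapping[seq]] += abundance
        for center, count in per_center.items():
            table.add(sample_id, center, count)
        denoised_counts[sample_id] = sum(per_center.values())
    cleaned, flagged = remove_bimeras(table, min_fold=bimera_min_fold)
    stats: dict[str, DenoiseStats] = {}
    for sample_id in prepared_by_sample:
        n_filtered = (
            n_filtered_by_sample[sample_id]
            if n_filtered_by_sample is not None
            else len(prepared_by_sample[sample_id])
        )
        stats[sample_id] = DenoiseStats(
            sample_id=sample_id,
            pool=pool,
            n_input=n_input_by_sample[sample_id],
            n_filtered=n_filtered,
            n_denoised=denoised_counts.get(sample_id, 0),
            n_nonchimeric=cleaned.sample_depth(sample_id),
        )
    return cleaned, flagged, stats


def write_asv_table(table: RawASVTable, tsv_path: str | Path, fasta_path: str | Path) -> None:
    """Write the features-x-samples TSV and the ASV FASTA."""
    df = table.to_frame()
    df.index.name = "asv_id"
    df.to_csv(tsv_path, sep="\t")
    with open(fasta_path, "w") as fh:
        for aid in sorted(table.sequences):
            fh.write(f">{aid}\n{table.sequences[aid]}\n")


def write_denoise_stats(stats: Iterable[DenoiseStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tpool\tn_input\tn_filtered\tn_denoised\t"
            "n_nonchimeric\tpass_ratio\n"
        )
        for s in stats:
            fh.write(
                f"{s.sample_id}\t{s.pool.value}\t{s.n_input}\t{s.n_filtered}\t"
                f"{s.n_denoised}\t{s.n_nonchimeric}\t{s.pass_ratio:.6f}\n"
            )
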