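"""Assign read pairs to the 16S or 18S pool by exclusive canonical k-mer votes.

Re-implementation of the reference-database read binning step: k-mers found in
only one of the two reference sets vote for that pool; shared k-mers carry no
information and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from ssumix.amplicon_io import ReadPair, revcomp
from ssumix.errors import ConfigurationError


class Pool(str, Enum):
    SSU16S = "SSU16S"
    SSU18S = "SSU18S"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class SplitDecision:
    pool: Pool
    votes_16S: int
    votes_18S: int


@dataclass(frozen=True)
class SplitIndex:
    """Exclusive canonical k-mer sets for the two reference pools."""

    k: int
    kmers_16S_only: frozenset[str]
    kmers_18S_only: frozenset[str]

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ConfigurationError("k must be odd (canonical k-mers)")
        if self.kmers_16S_only & self.kmers_18S_only:
            raise ConfigurationError("exclusive k-mer sets must be disjoint")


def canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield canonical k-mers (lexicographic min of k-mer and its reverse
    complement); k-mers containing non-ACGT characters are skipped."""
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    if set(seq) <= set("ACGT"):
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            rkmer = rc[n - k - i : n - i]
            yield kmer if kmer <= rkmer else rkmer
        return
    # prefix counts of invalid characters so each k-mer check is O(1)
    bad = [0]
    for c in seq:
        bad.append(bad[-1] + (c not in "ACGT"))
    for i in range(n - k + 1):
        if bad[i + k] - bad[i]:
            continue
        kmer = seq[i : i + k]
        rkmer = rc[n - k - i : n - i]
        yield kmer if kmer <= rkmer else rkmer


def _collect_kmers(fasta: str | Path, k: int) -> set[str]:
    kmers: set[str] = set()
    n_records = 0
    for record in SeqIO.parse(str(fasta), "fasta"):
        n_records += 1
        kmers.update(canonical_kmers(str(record.seq), k))
    if n_records == 0:
        raise ConfigurationError(f"reference FASTA {fasta} is empty")
    return kmers


def build_split_index(ref16S: str | Path, ref18S: str | Path, k: int = 31) -> SplitIndex:
    """Build the exclusive-k-mer index from two reference FASTA files."""
    k16 = _collect_kmers(ref16S, k)
    k18 = _collect_kmers(ref18S, k)
    shared = k16 & k18
    return SplitIndex(
        k=k,
        kmers_16S_only=frozenset(k16 - shared),
        kmers_18S_only=frozenset(k18 - shared),
    )


def split_pair(
    pair: ReadPair,
    index: SplitIndex,
    min_votes: int = 5,
    min_margin: float = 2.0,
) -> SplitDecision:
    """Vote each canonical k-mer of both mates against the exclusive sets.

    The winning pool must collect at least ``min_votes`` and at least
    ``min_margin`` times the loser's votes, otherwise UNASSIGNED.
    """
    v16 = 0
    v18 = 0
    in16 = index.kmers_16S_only
    in18 = index.kmers_18S_only
    for seq in (pair.fwd_seq, pair.rev_seq):
        for kmer in canonical_kmers(seq, index.k):
            if kmer in in16:
                v16 += 1
            elif kmer in in18:
                v18 += 1
    winner, loser = (v16, v18) if v16 >= v18 else (v18, v16)
    if v16 == v18 or winner < min_votes or winner < min_margin * loser:
        return SplitDecision(Pool.UNASSIGNED, v16, v18)
    return SplitDecision(Pool.SSU16S if v16 > v18 else Pool.SSU18S, v16, v18)


def split_reads(
    pairs: Iterable[ReadPair],
    index: SplitIndex,
    min_votes: int = 5,
    min_margin: float = 2.0,
) -> tuple[list[ReadPair], list[ReadPair], list[ReadPair]]:
    """Partition pairs into (pool16, pool18, unassigned) lists."""
    pool16: list[ReadPair] = []
    pool18: list[ReadPair] = []
    unassigned: list[ReadPair] = []
    for pair in pairs:
        decision = split_pair(pair, index, min_votes, min_margin)
        if decision.pool is Pool.SSU16S:
            pool16.append(pair)
        elif decision.pool is Pool.SSU18S:
            pool18.append(pair)
        else:
            unassigned.append(pair)
    return pool16, pool18, unassigned


def write_split_report(
    path: str | Path, rows: Iterable[tuple[str, int, int, int]]
) -> None:
    """Write the per-sample split report TSV (sample_id, n16S, n18S, n_unassigned)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tn16S\tn18S\tn_unassigned\n")
        for sample_id, n16, n18, nun in rows:
            fh.write(f"{sample_id}\t{n16}\t{n18}\t{nun}\n")
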