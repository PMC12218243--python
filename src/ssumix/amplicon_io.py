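"""FASTQ/FASTA plumbing, sample manifests, and degenerate-primer trimming.

All FASTQ readers/writers are gzip-aware and use Phred+33 quality encoding.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ssumix.errors import ConfigurationError, FormatError, UsageError

PHRED_OFFSET = 33

#: IUPAC nucleotide code -> set of matching unambiguous bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair, both written 5'->3' as synthesized."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ConfigurationError(f"{name} primer is empty")
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ConfigurationError(
                    f"{name} primer contains non-IUPAC characters: {sorted(bad)}"
                )


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record with per-base Phred qualities."""

    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: tuple[int, ...]
    rev_qual: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual):
            raise FormatError(f"{self.read_id}: forward seq/qual length mismatch")
        if len(self.rev_seq) != len(self.rev_qual):
            raise FormatError(f"{self.read_id}: reverse seq/qual length mismatch")
        for q in itertools.chain(self.fwd_qual, self.rev_qual):
            if not 0 <= q <= 60:
                raise FormatError(f"{self.read_id}: Phred value {q} outside [0, 60]")


@dataclass(frozen=True)
class SampleManifest:
    """One manifest row linking a sample to its FASTQ files and sequencing run."""

    sample_id: str
    fwd_path: Path
    rev_path: Path
    run_id: str


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_quals(qual_str: str, read_id: str) -> tuple[int, ...]:
    quals = tuple(ord(c) - PHRED_OFFSET for c in qual_str)
    if any(q < 0 or q > 60 for q in quals):
        raise FormatError(f"{read_id}: quality characters outside Phred+33 [0, 60]")
    return quals


def read_fastq_pairs(
    fwd_path: str | Path, rev_path: str | Path, sample_id: str = ""
) -> Iterator[ReadPair]:
    """Stream read pairs from two order-matched FASTQ files (plain or gzip).

    Raises :class:`FormatError` if the files have unequal record counts or a
    record is malformed (with its index in the message).
    """
    _SENTINEL = object()
    with _open_maybe_gzip(fwd_path) as fh, _open_maybe_gzip(rev_path) as rh:
        fwd_iter = FastqGeneralIterator(fh)
        rev_iter = FastqGeneralIterator(rh)
        for i, (fwd, rev) in enumerate(
            itertools.zip_longest(fwd_iter, rev_iter, fillvalue=_SENTINEL)
        ):
            if fwd is _SENTINEL or rev is _SENTINEL:
                raise FormatError(
                    f"record count mismatch between {fwd_path} and {rev_path} "
                    f"at record {i}"
                )
            try:
                ftitle, fseq, fqual = fwd
                rtitle, rseq, rqual = rev
            except ValueError as exc:  # pragma: no cover - iterator yields triples
                raise FormatError(f"malformed FASTQ record at index {i}") from exc
            read_id = ftitle.split()[0] if ftitle else f"record_{i}"
            try:
                yield ReadPair(
                    read_id=read_id,
                    fwd_seq=fseq.upper(),
                    rev_seq=rseq.upper(),
                    fwd_qual=_decode_quals(fqual, read_id),
                    rev_qual=_decode_quals(rqual, read_id),
                    sample_id=sample_id,
                )
            except FormatError as exc:
                raise FormatError(f"record {i}: {exc}") from exc


def write_fastq_pairs(
    pairs: Iterable[ReadPair], fwd_path: str | Path, rev_path: str | Path
) -> int:
    """Write read pairs to two FASTQ files; returns the number written."""
    n = 0
    with _open_maybe_gzip(fwd_path, "wt") as fh, _open_maybe_gzip(rev_path, "wt") as rh:
        for pair in pairs:
            fh.write(_fastq_record(pair.read_id, pair.fwd_seq, pair.fwd_qual))
            rh.write(_fastq_record(pair.read_id, pair.rev_seq, pair.rev_qual))
            n += 1
    return n


def _fastq_record(read_id: str, seq: str, qual: tuple[int, ...]) -> str:
    qstr = "".join(chr(q + PHRED_OFFSET) for q in qual)
    return f"@{read_id}\n{seq}\n+\n{qstr}\n"


def read_manifest(path: str | Path) -> list[SampleManifest]:
    """Parse a TSV sample manifest with header sample_id, fwd_path, rev_path, run_id."""
    rows: list[SampleManifest] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "fwd_path", "rev_path", "run_id"]
        if header != expected:
            raise FormatError(f"manifest header must be {expected}, got {header}")
        base = Path(path).parent
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"manifest row has {len(fields)} fields, expected 4")
            sample_id, fwd, rev, run_id = fields
            if sample_id in seen:
                raise FormatError(f"duplicate sample_id {sample_id!r} in manifest")
            seen.add(sample_id)
            rows.append(
                SampleManifest(sample_id, base / fwd, base / rev, run_id)
            )
    return rows


def iupac_match(pattern: str, window: str, max_mismatch: int = 0) -> bool:
    """True iff ``window`` matches the degenerate ``pattern`` with at most
    ``max_mismatch`` positions outside the pattern's allowed sets.

    An N in the window matches any pattern code.
    """
    if len(pattern) != len(window):
        raise UsageError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    mismatches = 0
    for p, w in zip(pattern.upper(), window.upper()):
        if w == "N":
            continue
        if w not in IUPAC_SETS[p]:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def find_primer(seq: str, primer: str, max_mismatch: int, slack: int) -> int | None:
    """Return the 0-based start of the first primer site within the first
    ``slack`` offsets, or None.
    """
    plen = len(primer)
    for offset in range(0, slack + 1):
        if offset + plen > len(seq):
            break
        if iupac_match(primer, seq[offset : offset + plen], max_mismatch):
            return offset
    return None


def trim_primers(
    pair: ReadPair,
    primers: PrimerPair,
    max_mismatch: int = 2,
    slack: int = 5,
) -> ReadPair | None:
    """Remove 5' primers (and any preceding bases) from both mates.

    The forward primer is searched at the start of the forward read and the
    reverse primer at the start of the reverse read, each within the first
    ``slack`` offsets. Returns None (pair rejected) if either site is absent;
    mates are kept or dropped together.
    """
    f_off = find_primer(pair.fwd_seq, primers.forward, max_mismatch, slack)
    if f_off is None:
        return None
    r_off = find_primer(pair.rev_seq, primers.reverse, max_mismatch, slack)
    if r_off is None:
        return None
    f_cut = f_off + len(primers.forward)
    r_cut = r_off + len(primers.reverse)
    return replace(
        pair,
        fwd_seq=pair.fwd_seq[f_cut:],
        fwd_qual=pair.fwd_qual[f_cut:],
        rev_seq=pair.rev_seq[r_cut:],
        rev_qual=pair.rev_qual[r_cut:],
    )
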