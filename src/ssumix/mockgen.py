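"""Mock-community read simulator: ground truth for every pipeline stage.

Simulates paired-end reads from a known molar mixture of pseudo-16S and
pseudo-18S reference sequences, with a single-parameter platform bias
(Bernoulli retention beta for 18S fragments, emulating the sequencer's
preference for shorter fragments), per-base substitution error, linearly
decaying qualities, and optional two-parent chimeras.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

from ssumix.amplicon_io import IUPAC_SETS, PrimerPair, ReadPair, revcomp
from ssumix.domain_splitter import Pool
from ssumix.errors import ConfigurationError

_BASES = "ACGT"


@dataclass(frozen=True)
class MockMember:
    ref_id: str
    pool: Pool
    molar_proportion: float


@dataclass
class MockSpec:
    """Ground-truth community composition and simulation parameters."""

    members: list[MockMember]
    n_read_pairs: int
    read_len: int = 250
    bias_18S: float = 1.0
    per_base_error: float = 0.0
    quality_model: tuple[int, int] = (38, 25)
    chimera_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(m.molar_proportion for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"molar proportions sum to {total}, expected 1"
            )
        if not 0.0 < self.bias_18S <= 1.0:
            raise ConfigurationError("bias_18S must be in (0, 1]")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    member_id: str
    pool: Pool
    is_chimera: bool


@dataclass
class TruthTable:
    """Per-read ground truth plus the implied pre-sequencing molar fractions."""

    reads: list[ReadTruth] = field(default_factory=list)
    molar_fraction_16S: float = 0.0
    molar_fraction_18S: float = 0.0
    n_drawn: int = 0
    n_bias_dropped: int = 0


def load_mock_references() -> dict[str, str]:
    """The shipped pseudo-16S/18S reference sequences (ref_id -> sequence)."""
    path = resources.files("ssumix").joinpath("data/mock_refs.fasta")
    with resources.as_file(path) as fasta:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}


def mock_reference_pools() -> dict[str, Pool]:
    """Pool of each shipped mock reference, by id convention (M16_*/M18_*)."""
    return {
        rid: Pool.SSU16S if rid.startswith("M16") else Pool.SSU18S
        for rid in load_mock_references()
    }


def _site_mismatches(pattern: str, window: str) -> int:
    return sum(
        w not in IUPAC_SETS[p] and w != "N"
        for p, w in zip(pattern.upper(), window.upper())
    )


def _best_site(ref: str, pattern: str, max_mismatch: int) -> int | None:
    """Leftmost best-scoring match position of a degenerate pattern; None if
    no window is within max_mismatch."""
    plen = len(pattern)
    best_pos: int | None = None
    best_mm = max_mismatch + 1
    n_best = 0
    for pos in range(len(ref) - plen + 1):
        mm = _site_mismatches(pattern, ref[pos : pos + plen])
        if mm < best_mm:
            best_mm, best_pos, n_best = mm, pos, 1
        elif mm == best_mm:
            n_best += 1
    if best_pos is None or best_mm > max_mismatch:
        return None
    if n_best > 1:
        warnings.warn(
            f"multiple equally good primer sites ({n_best}); leftmost chosen"
        )
    return best_pos


def _find_sites(
    ref_seq: str, primers: PrimerPair, max_mismatch: int
) -> tuple[int, int, int, int] | None:
    """(fwd_start, fwd_end, rev_start, rev_end) of the primer sites on the
    forward strand, the reverse primer matched as its reverse complement."""
    f_pos = _best_site(ref_seq, primers.forward, max_mismatch)
    if f_pos is None:
        return None
    rc_rev = revcomp(primers.reverse)
    r_pos = _best_site(ref_seq, rc_rev, max_mismatch)
    if r_pos is None:
        return None
    f_end = f_pos + len(primers.forward)
    if r_pos < f_end:
        return None
    return f_pos, f_end, r_pos, r_pos + len(rc_rev)


def extract_amplicon(
    ref_seq: str, primers: PrimerPair, max_mismatch: int = 2
) -> str | None:
    """In-silico PCR: the segment between (exclusive of) the two primer
    sites, or None if either site is absent."""
    sites = _find_sites(ref_seq, primers, max_mismatch)
    if sites is None:
        return None
    _, f_end, r_start, _ = sites
    return ref_seq[f_end:r_start]


def extract_fragment(
    ref_seq: str, primers: PrimerPair, max_mismatch: int = 2
) -> str | None:
    """The sequenced fragment: primer sites inclusive (reads start with the
    primer, as they come off the machine)."""
    sites = _find_sites(ref_seq, primers, max_mismatch)
    if sites is None:
        return None
    f_start, _, _, r_end = sites
    return ref_seq[f_start:r_end]


def _quality_profile(read_len: int, q_start: int, q_end: int) -> tuple[int, ...]:
    if read_len == 1:
        return (q_start,)
    qs = np.rint(np.linspace(q_start, q_end, read_len)).astype(int)
    return tuple(int(q) for q in qs)


def _mutate(seq: str, per_base_error: float, rng: np.random.Generator) -> str:
    if per_base_error <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < per_base_error)
    for i in hits:
        current = chars[i]
        alternatives = [b for b in _BASES if b != current]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_run(
    spec: MockSpec,
    references: Mapping[str, str],
    primers: PrimerPair,
    max_mismatch: int = 2,
    sample_id: str = "mock",
) -> tuple[list[ReadPair], TruthTable]:
    """Simulate one sequencing of the mock community.

    ``spec.n_read_pairs`` fragments are drawn per molar proportions; each 18S
    fragment is retained with probability ``bias_18S`` (the platform's length
    bias), so the emitted read count is at most the draw count. All
    randomness flows from ``spec.seed``.
    """
    fragments: dict[str, str] = {}
    for member in spec.members:
        if member.ref_id not in references:
            raise ConfigurationError(f"member {member.ref_id}: reference missing")
        frag = extract_fragment(references[member.ref_id], primers, max_mismatch)
        if frag is None:
            raise ConfigurationError(
                f"member {member.ref_id}: no amplicon for the given primers"
            )
        fragments[member.ref_id] = frag

    rng = np.random.default_rng(spec.seed)
    probs = np.array([m.molar_proportion for m in spec.members])
    molar16 = sum(m.molar_proportion for m in spec.members if m.pool is Pool.SSU16S)
    molar18 = sum(m.molar_proportion for m in spec.members if m.pool is Pool.SSU18S)
    truth = TruthTable(
        molar_fraction_16S=molar16,
        molar_fraction_18S=molar18,
        n_drawn=spec.n_read_pairs,
    )
    q_start, q_end = spec.quality_model
    pairs: list[ReadPair] = []
    for i in range(spec.n_read_pairs):
        is_chimera = spec.chimera_rate > 0 and rng.random() < spec.chimera_rate
        idx_a = int(rng.choice(len(spec.members), p=probs))
        member_a = spec.members[idx_a]
        if is_chimera:
            idx_b = int(rng.choice(len(spec.members), p=probs))
            member_b = spec.members[idx_b]
            frag_a = fragments[member_a.ref_id]
            frag_b = fragments[member_b.ref_id]
            brk = int(rng.integers(1, min(len(frag_a), len(frag_b))))
            fragment = frag_a[:brk] + frag_b[brk:]
            pool = member_a.pool
            member_id = f"chimera:{member_a.ref_id}+{member_b.ref_id}"
        else:
            fragment = fragments[member_a.ref_id]
            pool = member_a.pool
            member_id = member_a.ref_id
        if pool is Pool.SSU18S and rng.random() > spec.bias_18S:
            truth.n_bias_dropped += 1
            continue
        fwd = _mutate(fragment[: spec.read_len], spec.per_base_error, rng)
        rev = _mutate(revcomp(fragment)[: spec.read_len], spec.per_base_error, rng)
        read_id = f"{sample_id}_read{i}"
        pairs.append(
            ReadPair(
                read_id=read_id,
                fwd_seq=fwd,
                rev_seq=rev,
                fwd_qual=_quality_profile(len(fwd), q_start, q_end),
                rev_qual=_quality_profile(len(rev), q_start, q_end),
                sample_id=sample_id,
            )
        )
        truth.reads.append(ReadTruth(read_id, member_id, pool, is_chimera))
    return pairs, truth


def emit_chemistry(spec: MockSpec, unit_scale: float = 1000.0) -> tuple[float, float]:
    """Bioanalyzer-equivalent molar concentrations (conc_16S, conc_18S) of the
    mock pool: the true molar fractions times an arbitrary unit scale (the
    correction math is unit-invariant)."""
    molar16 = sum(m.molar_proportion for m in spec.members if m.pool is Pool.SSU16S)
    molar18 = sum(m.molar_proportion for m in spec.members if m.pool is Pool.SSU18S)
    return molar16 * unit_scale, molar18 * unit_scale


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmember_id\tpool\tis_chimera\n")
        for r in truth.reads:
            fh.write(f"{r.read_id}\t{r.member_id}\t{r.pool.value}\t{int(r.is_chimera)}\n")


def table1_fixture() -> list["RunChemistry"]:
    """Machine-readable run-chemistry rows from the published correction-factor
    table.

    Concentrations are nmole/L except the Southern Oceans and Gradients runs
    (pmole/L); units cancel in the fractions. Rows whose printed digit runs do
    not parse unambiguously are included but flagged ``parse_ambiguous`` and
    excluded from exact-value tests. The FRAM/MOSAiC run has no bioanalyzer
    trace and borrows the Southern Oceans factors.
    """
    from ssumix.correction_merge import RunChemistry

    return [
        RunChemistry("SOUTHERN_OCEANS", 1340.0, 335.1, 295010733, 34623340),
        RunChemistry("GRADIENTS_1_2", 3292.0, 638.5, 101174114, 7014632),
        RunChemistry("P16N_P16S", 6162.1, 2182.8, 42116230, 3082200),
        RunChemistry("GA03_GP13", 2052.0, 434.0, 44337637, 1342050,
                     parse_ambiguous=True),
        RunChemistry("I8_I9", 6162.1, 2185.2, 40226353, 2245860,
                     parse_ambiguous=True),
        RunChemistry("GA02_GA10", 124014.1, 34444.1, 21661905, 678869),
        RunChemistry("AMT19_AMT20_POTATOE", 5969.3, 1361.0, 12505672, 261220,
                     parse_ambiguous=True),
        RunChemistry("FRAM_MOSAIC", None, None, 24349430, 2035473,
                     borrowed_from="SOUTHERN_OCEANS"),
    ]


def make_even_spec(
    n_read_pairs: int,
    molar_16S: float = 0.5,
    bias_18S: float = 1.0,
    per_base_error: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
    references: Mapping[str, str] | None = None,
) -> MockSpec:
    """Convenience builder: all shipped members, molar mass split evenly
    within each pool, with the stated 16S:18S molar split."""
    pools = mock_reference_pools()
    ids16 = sorted(r for r, p in pools.items() if p is Pool.SSU16S)
    ids18 = sorted(r for r, p in pools.items() if p is Pool.SSU18S)
    members = [
        MockMember(r, Pool.SSU16S, molar_16S / len(ids16)) for r in ids16
    ] + [
        MockMember(r, Pool.SSU18S, (1.0 - molar_16S) / len(ids18)) for r in ids18
    ]
    return MockSpec(
        members=members,
        n_read_pairs=n_read_pairs,
        bias_18S=bias_18S,
        per_base_error=per_base_error,
        chimera_rate=chimera_rate,
        seed=seed,
    )
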