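"""Bioanalyzer-based correction factors and the 16S/18S table merge.

The sequencer under-samples the longer 18S fragments, so the post-split read
fractions are biased relative to the pre-sequencing molar fractions measured
on a bioanalyzer trace. Each pool's correction factor is its molar fraction
divided by its read fraction; raw counts are multiplied by the pool's factor
and divided by the sample's denoising pass ratio before the two pools are
merged into one quantitative table. Corrected counts are deliberately
non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ssumix.denoiser import DenoiseStats, RawASVTable
from ssumix.domain_splitter import Pool
from ssumix.errors import ConfigurationError

_TOL = 1e-9


def bio_fractions(conc_16S: float, conc_18S: float) -> tuple[float, float]:
    """Molar fractions of the two amplicon pools from bioanalyzer
    concentrations (any consistent unit; the quotient is unit-invariant)."""
    if conc_16S <= 0 or conc_18S <= 0:
        raise ConfigurationError("bioanalyzer concentrations must be > 0")
    total = conc_16S + conc_18S
    return conc_16S / total, conc_18S / total


def seq_fractions(seqs_16S: int, seqs_18S: int) -> tuple[float, float]:
    """Post-split read fractions of the two pools for a sequencing run."""
    total = seqs_16S + seqs_18S
    if total <= 0:
        raise ConfigurationError("total split read count must be > 0")
    return seqs_16S / total, seqs_18S / total


@dataclass
class RunChemistry:
    """Per-sequencing-run molar concentrations, split read totals, derived
    fractions, and the two correction factors.

    Runs without a bioanalyzer trace set ``borrowed_from`` to the run whose
    factors they adopt. ``parse_ambiguous`` marks fixture rows whose printed
    digit runs are not reliably machine-readable.
    """

    run_id: str
    conc_16S: float | None
    conc_18S: float | None
    seqs_16S: int
    seqs_18S: int
    borrowed_from: str | None = None
    parse_ambiguous: bool = False
    _resolved_bio: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def frac_16S_bio(self) -> float:
        return self._bio()[0]

    @property
    def frac_18S_bio(self) -> float:
        return self._bio()[1]

    def _bio(self) -> tuple[float, float]:
        if self._resolved_bio is not None:
            return self._resolved_bio
        if self.conc_16S is None or self.conc_18S is None:
            raise ConfigurationError(
                f"run {self.run_id}: no bioanalyzer data and borrowed_from "
                "not resolved"
            )
        return bio_fractions(self.conc_16S, self.conc_18S)

    @property
    def frac_16S_seq(self) -> float:
        return seq_fractions(self.seqs_16S, self.seqs_18S)[0]

    @property
    def frac_18S_seq(self) -> float:
        return seq_fractions(self.seqs_16S, self.seqs_18S)[1]


def correction_factors(
    chem: RunChemistry, chemistry_map: Mapping[str, RunChemistry] | None = None
) -> tuple[float, float]:
    """(cf_16S, cf_18S) for one run, each the quotient of the unrounded molar
    fraction over the unrounded read fraction.

    For a borrowed run the factors of the source run are returned verbatim
    (its own read fractions play no role).
    """
    if chem.borrowed_from is not None:
        if chemistry_map is None or chem.borrowed_from not in chemistry_map:
            raise ConfigurationError(
                f"run {chem.run_id}: borrowed_from={chem.borrowed_from!r} "
                "cannot be resolved"
            )
        source = chemistry_map[chem.borrowed_from]
        if source.borrowed_from is not None:
            raise ConfigurationError(
                f"run {chem.run_id}: borrowed_from chain is not allowed"
            )
        return correction_factors(source)
    cf16 = chem.frac_16S_bio / chem.frac_16S_seq
    cf18 = chem.frac_18S_bio / chem.frac_18S_seq
    return cf16, cf18


def check_weighted_identity(chem: RunChemistry) -> float:
    """Residual of cf16*fseq16 + cf18*fseq18 - 1 for a non-borrowed run."""
    cf16, cf18 = correction_factors(chem)
    return cf16 * chem.frac_16S_seq + cf18 * chem.frac_18S_seq - 1.0


def corrected_abundance(raw: float, cf: float, pass_ratio: float) -> float:
    """Raw count times the pool's correction factor over the sample's pass ratio."""
    if pass_ratio <= 0 or pass_ratio > 1:
        raise ConfigurationError(f"pass_ratio {pass_ratio} outside (0, 1]")
    return raw * cf / pass_ratio


@dataclass
class CorrectedASVTable:
    """Merged three-domain table of corrected (non-integer) abundances."""

    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    pools: dict[str, Pool] = field(default_factory=dict)  # asv_id -> pool
    provenance: dict[tuple[str, Pool], tuple[str, float, float]] = field(
        default_factory=dict
    )  # (sample, pool) -> (run_id, cf, pass_ratio)
    dropped_samples: list[str] = field(default_factory=list)

    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self.counts})

    def to_frame(self) -> pd.DataFrame:
        samples = self.sample_ids()
        asvs = sorted(self.sequences)
        df = pd.DataFrame(0.0, index=asvs, columns=samples)
        for (s, a), c in self.counts.items():
            df.at[a, s] = c
        return df


def merge_tables(
    t16: RawASVTable,
    t18: RawASVTable,
    chemistry: Mapping[str, RunChemistry],
    stats: Mapping[tuple[str, Pool], DenoiseStats],
    sample_runs: Mapping[str, str],
    min_depth: int = 5000,
) -> CorrectedASVTable:
    """Correct both pools and merge them into a single table.

    Samples whose combined raw post-denoise depth is strictly below
    ``min_depth`` are dropped before any correction (exactly min_depth is
    kept). Missing chemistry or stats for a retained sample is a hard error.
    """
    all_samples = sorted(set(t16.sample_ids()) | set(t18.sample_ids()))
    out = CorrectedASVTable()
    cf_cache: dict[str, tuple[float, float]] = {}
    for sample_id in all_samples:
        depth = t16.sample_depth(sample_id) + t18.sample_depth(sample_id)
        if depth < min_depth:
            out.dropped_samples.append(sample_id)
            continue
        if sample_id not in sample_runs:
            raise ConfigurationError(f"sample {sample_id}: no run_id mapping")
        run_id = sample_runs[sample_id]
        if run_id not in chemistry:
            raise ConfigurationError(
                f"sample {sample_id}: run {run_id} has no chemistry record"
            )
        if run_id not in cf_cache:
            cf_cache[run_id] = correction_factors(chemistry[run_id], chemistry)
        cf16, cf18 = cf_cache[run_id]
        for table, pool, cf in ((t16, Pool.SSU16S, cf16), (t18, Pool.SSU18S, cf18)):
            if table.sample_depth(sample_id) == 0:
                continue
            key = (sample_id, pool)
            if key not in stats:
                raise ConfigurationError(
                    f"sample {sample_id}: missing denoise stats for {pool.value}"
                )
            ratio = stats[key].pass_ratio
            out.provenance[key] = (run_id, cf, ratio)
            for (s, aid), raw in table.counts.items():
                if s != sample_id:
                    continue
                out.counts[(s, aid)] = corrected_abundance(raw, cf, ratio)
                out.sequences[aid] = table.sequences[aid]
                out.pools[aid] = pool
    return out


def read_chemistry_table(path: str | Path) -> dict[str, RunChemistry]:
    """Read a run-chemistry TSV with columns run_id, conc_16S, conc_18S,
    seqs_16S, seqs_18S, borrowed_from (empty if none)."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "borrowed_from": str})
    required = {"run_id", "conc_16S", "conc_18S", "seqs_16S", "seqs_18S"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"chemistry table missing columns {sorted(missing)}")
    out: dict[str, RunChemistry] = {}
    for row in df.itertuples(index=False):
        borrowed = getattr(row, "borrowed_from", None)
        if borrowed is not None and (pd.isna(borrowed) or borrowed == ""):
            borrowed = None
        conc16 = None if pd.isna(row.conc_16S) else float(row.conc_16S)
        conc18 = None if pd.isna(row.conc_18S) else float(row.conc_18S)
        out[row.run_id] = RunChemistry(
            run_id=row.run_id,
            conc_16S=conc16,
            conc_18S=conc18,
            seqs_16S=int(row.seqs_16S),
            seqs_18S=int(row.seqs_18S),
            borrowed_from=borrowed,
        )
    return out


def write_chemistry_report(
    chems: Iterable[RunChemistry],
    chemistry_map: Mapping[str, RunChemistry],
    path: str | Path,
) -> None:
    """Write the per-run chemistry report; fractions to 3 dp and correction
    factors to 2 dp for display (unrounded values are used in computation)."""
    with open(path, "w") as fh:
        fh.write(
            "run_id\tconc_16S\tconc_18S\tfrac_16S_bio\tfrac_18S_bio\t"
            "seqs_16S\tseqs_18S\tfrac_16S_seq\tfrac_18S_seq\tcf_16S\tcf_18S\t"
            "borrowed_from\n"
        )
        for chem in chems:
            cf16, cf18 = correction_factors(chem, chemistry_map)
            if chem.borrowed_from is None:
                bio = f"{chem.frac_16S_bio:.3f}\t{chem.frac_18S_bio:.3f}"
                conc = f"{chem.conc_16S}\t{chem.conc_18S}"
            else:
                bio = "NA\tNA"
                conc = "NA\tNA"
            fh.write(
                f"{chem.run_id}\t{conc}\t{bio}\t{chem.seqs_16S}\t{chem.seqs_18S}\t"
                f"{chem.frac_16S_seq:.3f}\t{chem.frac_18S_seq:.3f}\t"
                f"{cf16:.2f}\t{cf18:.2f}\t{chem.borrowed_from or ''}\n"
            )


def write_corrected_table(table: CorrectedASVTable, tsv_path: str | Path,
                          triplet_path: str | Path | None = None,
                          provenance_path: str | Path | None = None) -> None:
    """Write the merged corrected table (dense TSV, optional sparse triplets
    and provenance sidecar)."""
    df = table.to_frame()
    df.index.name = "asv_id"
    pool_col = pd.Series({a: table.pools[a].value for a in df.index}, name="pool")
    df_out = pd.concat([pool_col, df], axis=1)
    df_out.to_csv(tsv_path, sep="\t", float_format="%.6f")
    if triplet_path is not None:
        with open(triplet_path, "w") as fh:
            fh.write("sample_id\tasv_id\tpool\tcorrected_count\n")
            for (s, a), c in sorted(table.counts.items()):
                fh.write(f"{s}\t{a}\t{table.pools[a].value}\t{c:.6f}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            fh.write("sample_id\tpool\trun_id\tcorrection_factor\tpass_ratio\n")
            for (s, p), (run_id, cf, ratio) in sorted(table.provenance.items()):
                fh.write(f"{s}\t{p.value}\t{run_id}\t{cf:.6f}\t{ratio:.6f}\n")
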