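"""Naive-Bayes k-mer taxonomy, rank harmonization, and ecological rollups.

The classifier is a multinomial naive Bayes over k-mer counts with additive
smoothing and uniform taxon priors; per-rank confidence comes from bootstrap
resampling of the query's k-mers. Three reference rank schemes are
harmonized into one 10-column row (prokaryote-style, eukaryote-style, and a
cyanobacterial-ecotype scheme that contributes a single column).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ssumix.domain_splitter import Pool
from ssumix.errors import ConfigurationError

UNIFIED_COLUMNS = [
    "Domain", "Supergroup", "Division", "Phylum", "Class", "Order",
    "Family", "Genus", "Species", "Proportal_ASV_Ecotype",
]


class Scheme(str, Enum):
    SILVA_LIKE = "SILVA-like"
    PR2_LIKE = "PR2-like"
    PROPORTAL_LIKE = "ProPortal-like"


@dataclass(frozen=True)
class ReferenceTaxonomy:
    """Labeled reference sequences: (sequence, rank-path) pairs plus a scheme tag."""

    records: tuple[tuple[str, tuple[str, ...]], ...]
    scheme: Scheme

    def __post_init__(self) -> None:
        depths = {len(path) for _, path in self.records}
        if len(depths) > 1:
            raise ConfigurationError(
                f"inconsistent rank-path depths within scheme: {sorted(depths)}"
            )


@dataclass
class TaxonomyRecord:
    asv_id: str
    rank_path: tuple[str, ...]            # truncated at low-confidence ranks
    confidence_per_rank: tuple[float, ...]  # aligned to the *untruncated* depth
    source_scheme: Scheme
    proportal_ecotype: str | None = None


@dataclass
class NBModel:
    """Per-taxon k-mer log-likelihoods with additive smoothing."""

    k: int
    taxa: list[tuple[str, ...]]
    kmer_index: dict[str, int]
    log_likelihoods: np.ndarray  # shape (n_taxa, n_kmers + 1); last col = unseen
    scheme: Scheme


def _count_kmers(seq: str, k: int) -> Counter[str]:
    seq = seq.upper().replace("N", "")
    counts: Counter[str] = Counter()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if all(c in "ACGT" for c in kmer):
            counts[kmer] += 1
    return counts


def train_nb(ref: ReferenceTaxonomy, k: int = 8, pseudocount: float = 0.5) -> NBModel:
    """Fit the per-taxon smoothed k-mer model; taxa with identical rank-paths
    pool their sequences."""
    by_taxon: dict[tuple[str, ...], Counter[str]] = {}
    for seq, path in ref.records:
        by_taxon.setdefault(path, Counter()).update(_count_kmers(seq, k))
    if len(by_taxon) < 2:
        raise ConfigurationError("reference must contain at least 2 distinct taxa")
    vocabulary = sorted(set().union(*by_taxon.values()))
    kmer_index = {kmer: i for i, kmer in enumerate(vocabulary)}
    n_kmers = len(vocabulary)
    taxa = sorted(by_taxon)
    loglik = np.empty((len(taxa), n_kmers + 1))
    for t, taxon in enumerate(taxa):
        counts = np.full(n_kmers + 1, pseudocount)
        for kmer, c in by_taxon[taxon].items():
            counts[kmer_index[kmer]] += c
        loglik[t] = np.log(counts / counts.sum())
    return NBModel(k=k, taxa=taxa, kmer_index=kmer_index,
                   log_likelihoods=loglik, scheme=ref.scheme)


def _posteriors(model: NBModel, kmer_ids: np.ndarray) -> np.ndarray:
    scores = model.log_likelihoods[:, kmer_ids].sum(axis=1)
    scores -= scores.max()
    probs = np.exp(scores)
    return probs / probs.sum()


def query_kmer_ids(model: NBModel, sequence: str) -> np.ndarray:
    """Indices of the query's k-mers in the model vocabulary (unseen k-mers
    map to the shared smoothing column)."""
    unseen = len(model.kmer_index)
    counts = _count_kmers(sequence, model.k)
    ids: list[int] = []
    for kmer, c in counts.items():
        ids.extend([model.kmer_index.get(kmer, unseen)] * c)
    return np.asarray(ids, dtype=np.intp)


def classify_sequence(
    sequence: str,
    model: NBModel,
    n_bootstrap: int = 100,
    confidence: float = 0.7,
    seed: int = 0,
    asv_identifier: str = "",
) -> TaxonomyRecord:
    """Classify one sequence; per-rank confidence is the fraction of
    bootstrap k-mer subsamples whose winning rank-path agrees at that rank,
    and ranks below the confidence threshold are truncated (prefix-closed).

    Concatenation N-spacers are excised before k-merization. Sequences
    shorter than k (or all-N) come back unclassified.
    """
    ids = query_kmer_ids(model, sequence)
    if ids.size == 0:
        return TaxonomyRecord(asv_identifier, (), (), model.scheme)
    winner = model.taxa[int(np.argmax(_posteriors(model, ids)))]
    depth = len(winner)
    rng = np.random.default_rng(seed)
    agree = np.zeros(depth)
    size = max(1, ids.size // 8)  # classic bootstrap subsample of 1/8 of k-mers
    for _ in range(n_bootstrap):
        sample = rng.choice(ids, size=size, replace=True)
        boot_winner = model.taxa[int(np.argmax(_posteriors(model, sample)))]
        for r in range(depth):
            if r < len(boot_winner) and boot_winner[r] == winner[r]:
                agree[r] += 1
            else:
                break
    conf = tuple(float(a / n_bootstrap) for a in agree)
    keep = depth
    for r in range(depth):
        if conf[r] < confidence:
            keep = r
            break
    return TaxonomyRecord(asv_identifier, winner[:keep], conf, model.scheme)


def harmonize(record: TaxonomyRecord) -> dict[str, str]:
    """Map a scheme-specific rank-path onto the unified 10-column row.

    Prokaryote-style (7 ranks) fills Domain,Phylum,...,Species and leaves
    Supergroup/Division empty; eukaryote-style (8 ranks) fills
    Domain,Supergroup,Division,Class,...,Species and leaves Phylum empty;
    the ecotype scheme fills only Proportal_ASV_Ecotype.
    """
    row = {col: "" for col in UNIFIED_COLUMNS}
    path = record.rank_path
    if record.source_scheme is Scheme.SILVA_LIKE:
        targets = ["Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species"]
    elif record.source_scheme is Scheme.PR2_LIKE:
        targets = ["Domain", "Supergroup", "Division", "Class", "Order",
                   "Family", "Genus", "Species"]
    elif record.source_scheme is Scheme.PROPORTAL_LIKE:
        if path:
            row["Proportal_ASV_Ecotype"] = path[-1]
        elif record.proportal_ecotype:
            row["Proportal_ASV_Ecotype"] = record.proportal_ecotype
        return row
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown scheme {record.source_scheme}")
    for label, column in zip(path, targets):
        row[column] = label
    if record.proportal_ecotype:
        row["Proportal_ASV_Ecotype"] = record.proportal_ecotype
    return row


EcoRule = tuple[Callable[[dict[str, str], Pool], bool], str]


def default_eco_rules() -> list[EcoRule]:
    """Ordered first-match-wins rules reproducing the shipped plankton groups."""
    def col(row: dict[str, str], name: str) -> str:
        return row.get(name, "")

    return [
        (lambda r, p: col(r, "Domain") == "Archaea", "Archaea"),
        (lambda r, p: col(r, "Order") == "Chloroplast", "Chloroplast 16S"),
        (lambda r, p: col(r, "Class") == "Cyanobacteriia"
         or col(r, "Class") == "Cyanobacteria"
         or col(r, "Phylum") == "Cyanobacteria", "Cyanobacteria"),
        (lambda r, p: col(r, "Class") == "Alphaproteobacteria", "Alphaproteobacteria"),
        (lambda r, p: col(r, "Class") == "Gammaproteobacteria", "Gammaproteobacteria"),
        (lambda r, p: col(r, "Phylum") == "Bacteroidota", "Bacteroidota"),
        (lambda r, p: col(r, "Domain") == "Bacteria", "Other Bacteria"),
        (lambda r, p: p is Pool.SSU18S and col(r, "Division") == "Dinoflagellata",
         "Dinoflagellates"),
        (lambda r, p: p is Pool.SSU18S and col(r, "Supergroup") != "",
         "Other Eukaryotes"),
    ]


def assign_eco_group(
    row: dict[str, str], pool: Pool, rules: Sequence[EcoRule] | None = None
) -> str:
    """First matching rule wins; default label is "Other"."""
    if rules is None:
        rules = default_eco_rules()
    for predicate, label in rules:
        if predicate(row, pool):
            return label
    return "Other"


def ecotype_reannotate(
    records: Mapping[str, TaxonomyRecord],
    sequences: Mapping[str, str],
    proportal_ref: ReferenceTaxonomy,
    is_cyano: Callable[[dict[str, str]], bool] | None = None,
    k: int = 8,
    n_bootstrap: int = 100,
    confidence: float = 0.7,
    seed: int = 0,
) -> dict[str, TaxonomyRecord]:
    """Second classification pass of the cyanobacterial subset against an
    ecotype-resolving reference; non-cyanobacterial records are untouched."""
    if is_cyano is None:
        is_cyano = lambda row: assign_eco_group(row, Pool.SSU16S) == "Cyanobacteria"
    if not proportal_ref.records:
        import warnings

        warnings.warn("empty ecotype reference; re-annotation skipped")
        return dict(records)
    model = train_nb(proportal_ref, k=k)
    out: dict[str, TaxonomyRecord] = {}
    for aid, record in records.items():
        row = harmonize(record)
        if is_cyano(row) and aid in sequences:
            eco = classify_sequence(
                sequences[aid], model, n_bootstrap, confidence, seed=seed,
                asv_identifier=aid,
            )
            record = TaxonomyRecord(
                asv_id=record.asv_id,
                rank_path=record.rank_path,
                confidence_per_rank=record.confidence_per_rank,
                source_scheme=record.source_scheme,
                proportal_ecotype=eco.rank_path[-1] if eco.rank_path else None,
            )
        out[aid] = record
    return out


def read_reference_taxonomy(
    fasta_path, tsv_path, scheme: Scheme
) -> ReferenceTaxonomy:
    """Load labeled references: FASTA plus a TSV of (seq_id, semicolon rank path)."""
    from Bio import SeqIO

    paths: dict[str, tuple[str, ...]] = {}
    with open(tsv_path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            seq_id, path = line.rstrip("\n").split("\t")
            paths[seq_id] = tuple(path.split(";"))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in paths:
            raise ConfigurationError(f"sequence {rec.id} missing from rank-path TSV")
        records.append((str(rec.seq), paths[rec.id]))
    return ReferenceTaxonomy(records=tuple(records), scheme=scheme)


def write_unified_taxonomy(
    rows: Mapping[str, dict[str, str]],
    eco_groups: Mapping[str, str],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("asv_id\t" + "\t".join(UNIFIED_COLUMNS) + "\tEco_relevant_plank_groups\n")
        for aid in sorted(rows):
            row = rows[aid]
            fh.write(
                aid + "\t" + "\t".join(row[c] for c in UNIFIED_COLUMNS)
                + f"\t{eco_groups.get(aid, 'Other')}\n"
            )
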