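# ssumix

A three-domain (bacteria + archaea + eukaryote) rRNA metabarcoding pipeline
for amplicons produced with the universal 515Y/926R primer pair, which
amplifies 16S and 18S rRNA simultaneously. The pipeline:

1. **trims** the degenerate primers off demultiplexed paired-end FASTQ reads,
2. **splits** each read pair into a 16S pool, an 18S pool, or unassigned, by
   exclusive canonical k-mer votes against two reference FASTA sets,
3. **prepares** each pool appropriately — 16S pairs are overlap-merged, while
   the longer, non-overlapping 18S pairs are truncated to fixed lengths
   (220 bp forward / 180 bp reverse) and concatenated around an N spacer —
   after expected-error (MaxEE ≤ 2) filtering,
4. **denoises** prepared sequences into ASVs with a deterministic greedy
   abundance-skew algorithm and removes two-parent bimeras,
5. **corrects and merges** the two ASV tables into one quantitative table:
   each pool's counts are multiplied by a run-level correction factor
   (bioanalyzer molar fraction ÷ post-split read fraction, undoing the
   sequencer's bias against longer 18S fragments) and divided by the
   per-sample denoising pass ratio; samples below 5,000 reads are dropped,
6. **classifies** ASVs with a bootstrap naive-Bayes k-mer classifier,
   harmonizes three reference rank schemes into one 10-column taxonomy, and
   rolls ASVs up into ecologically relevant plankton groups,
7. attaches **oceanographic context** (euphotic depth 4.6/Kd490, Longhurst
   province from GeoJSON polygons, hemisphere-aware season) and computes
   group-level relative-abundance summaries.

A mock-community simulator (`ssumix.mockgen`) generates paired-end reads with
known molar composition, a tunable 18S retention bias β, per-base error,
and injected chimeras, so every stage is testable without downloads.

## Test

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests, and
`tests/test_acceptance.py` (one test per acceptance criterion, including a
50,000-pair ratio-recovery simulation and a 20-sample re-sequencing
robustness check; the full run takes a few minutes on one CPU).

## CLI

```bash
# simulate a mock run (writes FASTQ pairs, truth, chemistry, manifest)
ssumix simulate --out mock/ --n-pairs 10000 --molar-16s 0.667 \
    --bias-18s 0.25 --error-rate 0.001 --seed 1

# end-to-end: trim -> split -> prep -> denoise -> correct/merge
ssumix all --manifest mock/manifest.tsv --ref-16s ref16.fasta \
    --ref-18s ref18.fasta --chemistry mock/chemistry_conc.tsv \
    --out results/ --seed 1

# individual stages
ssumix split | prep | denoise | correct | classify | summarize
```

All knobs (k-mer size, vote thresholds, MaxEE, trim lengths, denoiser alpha,
minimum depth, …) live in a YAML config passed with `--config`; unknown keys
are rejected and every output directory gets a `run_info.json` stamping the
resolved config hash and package version. Runs without bioanalyzer data can
declare `borrowed_from` in the chemistry TSV to adopt another run's
correction factors.

Outputs are TSVs: split report, denoise statistics (including the per-sample
pass ratio), per-run chemistry report (fractions to 3 dp, correction factors
to 2 dp), the merged corrected table (dense + sparse triplets, non-integer
values by design), a provenance sidecar, and the unified taxonomy table.

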