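import itertools
import random

import pytest

from ssumix.denoiser import (
    DenoiseStats,
    RawASVTable,
    asv_id,
    compute_pass_ratio,
    denoise_greedy,
    denoise_samples,
    dereplicate,
    is_bimera_of,
    remove_bimeras,
)
from ssumix.domain_splitter import Pool
from ssumix.errors import UsageError
from ssumix.read_prep import PreparedSequence


def prep(seqs, sample="s1", pool=Pool.SSU16S):
    return [
        PreparedSequence(sample, pool, s, (30,) * len(s)) for s in seqs
    ]


class TestDereplicate:
    def test_basic(self):
        assert dereplicate(prep(["AAA", "AAA", "CCC"])) == [("AAA", 2), ("CCC", 1)]

    def test_empty(self):
        assert dereplicate([]) == []

    def test_tie_broken_lexicographically(self):
        out = dereplicate(prep(["TTT", "AAA"]))
        assert out == [("AAA", 1), ("TTT", 1)]

    def test_template_counting_oracle(self):
        rng = random.Random(0)
        templates = ["ACGTACGT", "TTGGCCAA", "GATCGATC"]
        reads = [rng.choice(templates) for _ in range(100)]
        out = dereplicate(prep(reads))
        assert sum(c for _, c in out) == 100
        assert {s: c for s, c in out} == {
            t: reads.count(t) for t in set(reads)
        }


class TestDenoiseGreedy:
    def test_singleton_merges_into_big_center(self):
        # d=1, alpha=2: threshold 1000 / 2^3 = 125 >= 1 -> merge
        derep = [("AAAAAAAA", 1000), ("AAAAAAAT", 1)]
        mapping = denoise_greedy(derep, alpha=2.0)
        assert mapping["AAAAAAAT"] == "AAAAAAAA"

    def test_balanced_pair_stays_two_centers(self):
        # 500 > 1000 / 8 = 125 -> new center
        derep = [("AAAAAAAA", 1000), ("AAAAAAAT", 500)]
        mapping = denoise_greedy(derep, alpha=2.0)
        assert mapping["AAAAAAAT"] == "AAAAAAAT"

    def test_unequal_lengths_never_merge(self):
        derep = [("AAAAAAAA", 1000), ("AAAAAAA", 1)]
        mapping = denoise_greedy(derep, alpha=2.0)
        assert mapping["AAAAAAA"] == "AAAAAAA"

    def test_error_free_templates_stay_distinct(self):
        rng = random.Random(4)
        templates = {
            "".join(rng.choice("ACGT") for _ in range(60)) for _ in range(6)
        }
        reads = list(
            itertools.chain.from_iterable([t] * rng.randint(5, 50) for t in templates)
        )
        derep = dereplicate(prep(reads))
        mapping = denoise_greedy(derep)
        assert set(mapping.values()) == templates

    def test_distance_beyond_max_dist_is_new_center(self):
        a = "A" * 40
        b = "A" * 29 + "T" * 11  # d = 11 > max_dist 10
        mapping = denoise_greedy([(a, 100000), (b, 1)], max_dist=10)
        assert mapping[b] == b

    def test_deterministic(self):
        derep = [("AAAA", 10), ("AAAT", 10), ("AATT", 3)]
        m1 = denoise_greedy(derep)
        m2 = denoise_greedy(list(derep))
        assert m1 == m2


def oracle_bimera_flags(sequences, totals, min_fold=2.0):
    """Exhaustive search over all parent pairs and breakpoints."""
    flagged = set()
    for child, cseq in sequences.items():
        n = len(cseq)
        parents = [
            a for a in sequences
            if a != child and totals[a] >= min_fold * totals[child]
        ]
        for pa, pb in itertools.product(parents, repeat=2):
            sa, sb = sequences[pa], sequences[pb]
            for brk in range(1, n):
                if len(sa) < brk or len(sb) < n - brk:
                    continue
                if cseq[:brk] == sa[:brk] and cseq[brk:] == sb[len(sb) - (n - brk):]:
                    flagged.add(child)
                    break
            if child in flagged:
                break
    return flagged


class TestRemoveBimeras:
    def _table(self, seq_counts, pool=Pool.SSU16S):
        table = RawASVTable(pool=pool)
        for seq, count in seq_counts.items():
            table.add("s1", seq, count)
        return table

    def test_constructed_bimera_flagged(self):
        rng = random.Random(10)
        a = "".join(rng.choice("ACGT") for _ in range(220))
        b = "".join(rng.choice("ACGT") for _ in range(220))
        child = a[:100] + b[100:]
        table = self._table({a: 100, b: 100, child: 10})
        cleaned, flagged = remove_bimeras(table)
        assert flagged == [asv_id(child)]
        assert asv_id(child) not in cleaned.sequences
        assert asv_id(a) in cleaned.sequences

    def test_single_asv_nothing_flagged(self):
        table = self._table({"ACGTACGTAC": 50})
        _, flagged = remove_bimeras(table)
        assert flagged == []

    def test_low_abundance_parents_do_not_flag(self):
        rng = random.Random(11)
        a = "".join(rng.choice("ACGT") for _ in range(80))
        b = "".join(rng.choice("ACGT") for _ in range(80))
        child = a[:40] + b[40:]
        # parents only 1.5x the child: below the 2x requirement
        table = self._table({a: 15, b: 15, child: 10})
        _, flagged = remove_bimeras(table)
        assert flagged == []

    def test_unequal_length_parents_suffix_end_aligned(self):
        a = "AAAACCCCGGGGTTTTAAAA"
        b = "TTTTGGGGCCCCAAAATTTTGGGG"  # longer than child
        child = a[:10] + b[-10:]
        table = self._table({a: 40, b: 40, child: 5})
        _, flagged = remove_bimeras(table)
        assert asv_id(child) in flagged

    @pytest.mark.parametrize("seed", range(4))
    def test_five_asv_toy_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        base = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in range(3)]
        seqs = list(base)
        # add two children spliced from the base set
        seqs.append(base[0][:12] + base[1][12:])
        seqs.append(base[2][:7] + base[0][-23:])
        counts = {s: rng.choice([5, 40, 80]) for s in seqs}
        table = self._table(counts)
        _, flagged = remove_bimeras(table)
        ids = {asv_id(s): s for s in seqs}
        totals = {aid: counts[ids[aid]] for aid in ids}
        expected = oracle_bimera_flags(
            {aid: ids[aid] for aid in ids}, totals
        )
        assert set(flagged) == expected


class TestPassRatio:
    def test_direct_quotient(self):
        stats = DenoiseStats("s1", Pool.SSU16S, 1000, 950, 950, 900)
        assert compute_pass_ratio(stats) == pytest.approx(0.9)

    def test_lossless_run_is_one(self):
        stats = DenoiseStats("s1", Pool.SSU16S, 500, 500, 500, 500)
        assert compute_pass_ratio(stats) == 1.0

    def test_zero_input_flagged(self):
        with pytest.raises(UsageError, match="unusable"):
            compute_pass_ratio(DenoiseStats("s1", Pool.SSU16S, 0, 0, 0, 0))

    def test_counts_must_be_non_increasing(self):
        with pytest.raises(UsageError):
            DenoiseStats("s1", Pool.SSU16S, 100, 200, 100, 100)

    def test_mock_injected_chimeras(self, mock_refs, primers):
        """Pass ratio tracks the truth table's effective chimera fraction."""
        from ssumix.amplicon_io import trim_primers
        from ssumix.mockgen import MockMember, MockSpec, simulate_run
        from ssumix.read_prep import prepare_pool

        members = [
            MockMember("M16_1", Pool.SSU16S, 0.4),
            MockMember("M16_2", Pool.SSU16S, 0.35),
            MockMember("M16_3", Pool.SSU16S, 0.25),
        ]
        spec = MockSpec(members=members, n_read_pairs=2000, chimera_rate=0.05,
                        seed=77)
        pairs, truth = simulate_run(spec, mock_refs, primers)
        # effective chimeras: reads whose two parents actually differ
        effective = sum(
            1 for t in truth.reads
            if t.is_chimera and len(set(t.member_id[8:].split("+"))) == 2
        )
        trimmed = [trim_primers(p, primers) for p in pairs]
        trimmed = [p for p in trimmed if p is not None]
        prepared, _ = prepare_pool(trimmed, Pool.SSU16S, "s1")
        table, flagged, stats = denoise_samples(
            {"s1": prepared}, Pool.SSU16S, {"s1": len(trimmed)}
        )
        ratio = stats["s1"].pass_ratio
        assert ratio == pytest.approx(1.0 - effective / len(trimmed), abs=0.02)


class TestDenoiseSamples:
    def test_asv_ids_stable_across_runs(self, mock_refs, primers):
        from ssumix.amplicon_io import trim_primers
        from ssumix.mockgen import make_even_spec, simulate_run
        from ssumix.read_prep import prepare_pool

        spec = make_even_spec(300, molar_16S=1.0, per_base_error=0.002, seed=5)
        pairs, _ = simulate_run(spec, mock_refs, primers)
        trimmed = [p for p in (trim_primers(p, primers) for p in pairs) if p]
        prepared, _ = prepare_pool(trimmed, Pool.SSU16S, "s1")
        t1, _, _ = denoise_samples({"s1": prepared}, Pool.SSU16S, {"s1": len(trimmed)})
        t2, _, _ = denoise_samples({"s1": list(prepared)}, Pool.SSU16S,
                                   {"s1": len(trimmed)})
        assert t1.counts == t2.counts
        assert t1.sequences == t2.sequences

    def test_exact_recovery_of_true_amplicons(self, mock_refs, primers):
        """0.1% error, >100x coverage: ASVs equal the true amplicon set."""
        from ssumix.amplicon_io import trim_primers
        from ssumix.mockgen import extract_fragment, make_even_spec, simulate_run
        from ssumix.read_prep import prepare_pool

        spec = make_even_spec(4000, molar_16S=1.0, per_base_error=0.001, seed=6)
        pairs, _ = simulate_run(spec, mock_refs, primers)
        trimmed = [p for p in (trim_primers(p, primers) for p in pairs) if p]
        prepared, _ = prepare_pool(trimmed, Pool.SSU16S, "s1")
        table, _, _ = denoise_samples({"s1": prepared}, Pool.SSU16S,
                                      {"s1": len(trimmed)})
        truth_amplicons = set()
        for rid in ("M16_1", "M16_2", "M16_3", "M16_4", "M16_5"):
            frag = extract_fragment(mock_refs[rid], primers)
            truth_amplicons.add(frag[19:-20])  # primer-trimmed amplicon
        assert set(table.sequences.values()) == truth_amplicons

    def test_column_sums_equal_nonchimeric(self, mock_refs, primers):
        from ssumix.amplicon_io import trim_primers
        from ssumix.mockgen import make_even_spec, simulate_run
        from ssumix.read_prep import prepare_pool

        spec = make_even_spec(400, molar_16S=1.0, chimera_rate=0.04, seed=12)
        pairs, _ = simulate_run(spec, mock_refs, primers)
        trimmed = [p for p in (trim_primers(p, primers) for p in pairs) if p]
        prepared, _ = prepare_pool(trimmed, Pool.SSU16S, "s1")
        table, _, stats = denoise_samples({"s1": prepared}, Pool.SSU16S,
                                          {"s1": len(trimmed)})
        assert table.sample_depth("s1") == stats["s1"].n_nonchimeric
        assert stats["s1"].n_input - stats["s1"].n_nonchimeric >= 0


class TestAsvId:
    def test_case_insensitive_content_hash(self):
        assert asv_id("acgt") == asv_id("ACGT")
        assert asv_id("ACGT") != asv_id("ACGA")
        assert len(asv_id("ACGT")) == 32
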