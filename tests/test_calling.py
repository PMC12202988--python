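"""Stage-1 SNP calling: het k-mer extraction, pairing, support length,
maximum-weight matching and the end-to-end caller."""

import itertools
import warnings

import numpy as np
import pytest

import kinsketch as ks
from kinsketch.calling import CandidatePair, HetKmerSet, _extend
from kinsketch.kmers import KmerCountTable
from kinsketch.params import Params
from kinsketch.spectrum import HetRegion


def het_from_strings(seqs, k):
    return HetKmerSet.from_codes(
        (ks.canonical_kmer(s).code for s in seqs), k
    )


class TestExtractHetKmers:
    def test_interval_filter(self):
        table = KmerCountTable.from_dict({10: 1, 20: 6, 30: 19}, k=21)
        region = HetRegion(lo=6, hi=18, het_peak=12)
        het = ks.extract_het_kmers(table, region)
        assert set(int(c) for c in het.codes) == {20}

    def test_empty_result_warns(self):
        table = KmerCountTable.from_dict({10: 4, 20: 6}, k=21)
        with pytest.warns(UserWarning, match="no heterozygous"):
            het = ks.extract_het_kmers(table, HetRegion(lo=2, hi=3, het_peak=2))
        assert len(het) == 0

    def test_idempotent(self):
        table = KmerCountTable.from_dict({i: i % 7 + 2 for i in range(1, 40)}, k=21)
        region = HetRegion(lo=3, hi=5, het_peak=4)
        first = ks.extract_het_kmers(table, region)
        sub = KmerCountTable(
            first.codes,
            np.array([table.get(int(c)) for c in first.codes], dtype=np.int64),
            21,
        )
        second = ks.extract_het_kmers(sub, region)
        assert set(map(int, second.codes)) == set(map(int, first.codes))


class TestFindCandidatePairs:
    def test_middle_difference_found(self, p5):
        het = het_from_strings(["AACGT", "AATGT"], 5)
        pairs = ks.find_candidate_pairs(het, p5)
        assert len(pairs) == 1
        a = ks.kmers.decode_kmer(pairs[0].oriented_a, 5)
        b = ks.kmers.decode_kmer(pairs[0].oriented_b, 5)
        assert sum(x != y for x, y in zip(a, b)) == 1
        assert a[2] != b[2]

    def test_reverse_complement_orientation_found(self, p5):
        # revcomp("ACATT") = "AATGT" differs from "AACGT" only at the middle
        het = het_from_strings(["AACGT", "ACATT"], 5)
        pairs = ks.find_candidate_pairs(het, p5)
        assert len(pairs) == 1

    def test_non_middle_difference_rejected(self, p5):
        het = het_from_strings(["AACGT", "TACGT"], 5)
        assert ks.find_candidate_pairs(het, p5) == []

    def test_brute_force_equivalence_on_random_sets(self, p5):
        rng = np.random.default_rng(21)

        def middle_pair(x, y):
            for a in (x, ks.kmers.decode_kmer(ks.kmers.revcomp_code(ks.kmers.encode_kmer(x), 5), 5)):
                for b in (y, ks.kmers.decode_kmer(ks.kmers.revcomp_code(ks.kmers.encode_kmer(y), 5), 5)):
                    diff = [i for i in range(5) if a[i] != b[i]]
                    if diff == [2]:
                        return True
            return False

        for _ in range(20):
            seqs = {
                "".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(12)
            }
            het = het_from_strings(seqs, 5)
            got = {
                (p.kmer_a, p.kmer_b) for p in ks.find_candidate_pairs(het, p5)
            }
            canon = {s: ks.canonical_kmer(s).code for s in seqs}
            expected = set()
            for x, y in itertools.combinations(sorted(seqs), 2):
                if canon[x] != canon[y] and middle_pair(x, y):
                    expected.add(tuple(sorted((canon[x], canon[y]))))
            assert got == expected

    def test_deterministic_order(self, p5):
        het = het_from_strings(["AACGT", "AATGT", "CCCGA", "CCTGA"], 5)
        a = ks.find_candidate_pairs(het, p5)
        b = ks.find_candidate_pairs(het, p5)
        assert [(p.kmer_a, p.kmer_b) for p in a] == [(p.kmer_a, p.kmer_b) for p in b]
        assert [(p.kmer_a, p.kmer_b) for p in a] == sorted(
            (p.kmer_a, p.kmer_b) for p in a
        )


def windows(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class TestSupportLength:
    def test_full_support(self, p5):
        # both 9-bp allele contexts fully represented -> support = k
        ref_ctx, alt_ctx = "ACGTACGTA", "ACGTTCGTA"
        het = het_from_strings(windows(ref_ctx, 5) + windows(alt_ctx, 5), 5)
        pairs = ks.find_candidate_pairs(het, p5)
        central = [
            p for p in pairs
            if ks.support_length(p, het, p5) == 5
        ]
        assert len(central) >= 1

    def test_no_extension(self, p5):
        het = het_from_strings(["AACGT", "AATGT"], 5)
        (pair,) = ks.find_candidate_pairs(het, p5)
        assert ks.support_length(pair, het, p5) == 1

    def test_ambiguous_extension_stops(self, p5):
        # two right-extension bases both succeed -> walk stops, support 1
        seqs = ["AACGT", "AATGT"]
        for c in ("A", "C"):
            seqs.append("ACGT" + c)
            seqs.append("ATGT" + c)
        het = het_from_strings(seqs, 5)
        pairs = ks.find_candidate_pairs(het, p5)
        pair = next(
            p for p in pairs
            if {p.kmer_a, p.kmer_b}
            == {ks.canonical_kmer("AACGT").code, ks.canonical_kmer("AATGT").code}
        )
        assert ks.support_length(pair, het, p5) == 1

    def test_symmetric_under_allele_swap(self, p5):
        ref_ctx, alt_ctx = "ACGTACGTA", "ACGTTCGTA"
        het = het_from_strings(windows(ref_ctx, 5) + windows(alt_ctx, 5), 5)
        for p in ks.find_candidate_pairs(het, p5):
            swapped = CandidatePair(
                kmer_a=p.kmer_a, kmer_b=p.kmer_b,
                oriented_a=p.oriented_b, oriented_b=p.oriented_a,
            )
            assert ks.support_length(p, het, p5) == ks.support_length(swapped, het, p5)

    def test_invariant_under_reverse_complement(self, p5, pair_key):
        ref_ctx, alt_ctx = "ACGTACGTA", "ACGTTCGTA"
        rc = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for ctxs in ((ref_ctx, alt_ctx), (rc(ref_ctx), rc(alt_ctx))):
            het = het_from_strings(windows(ctxs[0], 5) + windows(ctxs[1], 5), 5)
            sups = sorted(
                ks.support_length(p, het, p5) for p in ks.find_candidate_pairs(het, p5)
            )
            if ctxs[0] == ref_ctx:
                fwd = sups
            else:
                assert sups == fwd


def brute_force_max_matching(edges):
    """Exhaustive optimum over all matchings (small graphs only).

    Recurses over vertices (lowest first: leave it unmatched or match it
    to any free neighbour), memoized on the remaining vertex set.
    """
    from functools import lru_cache

    adj = {}
    weight = {}
    for a, b, w in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
        weight[frozenset((a, b))] = w

    @lru_cache(maxsize=None)
    def rec(remaining: frozenset) -> int:
        if not remaining:
            return 0
        v = min(remaining)
        best = rec(remaining - {v})
        for u in adj.get(v, ()) & remaining:
            best = max(
                best, weight[frozenset((v, u))] + rec(remaining - {v, u})
            )
        return best

    return rec(frozenset(adj))


def pairs_from_edges(edges):
    return [
        CandidatePair(kmer_a=min(a, b), kmer_b=max(a, b),
                      oriented_a=min(a, b), oriented_b=max(a, b), support=w)
        for a, b, w in edges
    ]


class TestMaxWeightMatching:
    def test_path_graph(self):
        sel = ks.max_weight_matching(pairs_from_edges([(1, 2, 3), (2, 3, 2)]))
        assert [(p.kmer_a, p.kmer_b) for p in sel] == [(1, 2)]

    def test_disjoint_pairs_both_kept(self):
        sel = ks.max_weight_matching(pairs_from_edges([(1, 2, 3), (3, 4, 2)]))
        assert {(p.kmer_a, p.kmer_b) for p in sel} == {(1, 2), (3, 4)}

    def test_triangle_deterministic(self):
        edges = [(1, 2, 3), (1, 3, 3), (2, 3, 2)]
        sel = ks.max_weight_matching(pairs_from_edges(edges))
        assert [(p.kmer_a, p.kmer_b) for p in sel] == [(1, 2)]

    def test_equals_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(2, 13))
            edges = []
            for a, b in itertools.combinations(range(n), 2):
                if rng.random() < 0.4:
                    edges.append((a, b, int(rng.integers(1, 22))))
            if not edges:
                continue
            sel = ks.max_weight_matching(pairs_from_edges(edges))
            got = sum(p.support for p in sel)
            used = [k for p in sel for k in (p.kmer_a, p.kmer_b)]
            assert len(used) == len(set(used))  # valid matching
            assert got == brute_force_max_matching(edges)

    def test_greedy_fallback_is_valid(self):
        params = Params(matching_exact_max_nodes=4)
        edges = [(i, i + 1, (i % 5) + 1) for i in range(12)]
        sel = ks.max_weight_matching(pairs_from_edges(edges), params)
        used = [k for p in sel for k in (p.kmer_a, p.kmer_b)]
        assert len(used) == len(set(used))
        assert sel  # something selected


class TestCallSnps:
    def test_simulated_calls_and_precision(self, small_world, small_stage1, pair_key):
        truth_keys = {
            pair_key(t.ref_context, t.alt_context) for t in small_world.truth
        }
        calls = small_stage1.calls
        assert len(calls) > 0
        tp = sum(
            1 for c in calls if pair_key(c.ref_context, c.alt_context) in truth_keys
        )
        assert tp / len(calls) >= 0.90
        assert all(c.support == 21 for c in calls)

    def test_contexts_differ_only_at_center(self, small_stage1):
        k = 21
        for c in small_stage1.calls[:200]:
            diffs = [
                i for i in range(2 * k - 1) if c.ref_context[i] != c.alt_context[i]
            ]
            assert diffs == [k - 1]

    def test_read_order_invariance(self, small_reads):
        rng = np.random.default_rng(41)
        shuffled = list(small_reads)
        rng.shuffle(shuffled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ks.call_snps(small_reads)
            b = ks.call_snps(shuffled)
        assert [(c.ref_context, c.alt_context) for c in a] == [
            (c.ref_context, c.alt_context) for c in b
        ]

    def test_no_planted_snps_yields_no_or_few_calls(self):
        truth = ks.simulate_diploid(100_000, 0.0, seed=9)
        reads = ks.simulate_reads(truth, 10, 150, 0.0, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                calls = ks.call_snps(reads)
            except (RuntimeError, ks.NoPeakError):
                calls = []
        assert len(calls) <= 5
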