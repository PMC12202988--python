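"""Canonical encoding, reversible hashing, counting and histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kinsketch as ks
from kinsketch.kmers import (
    AmbiguousBaseError,
    KmerCountTable,
    decode_kmer,
    encode_kmer,
    invertible_hash_array,
    revcomp_code,
    sequences_to_codes,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=31)


class TestCanonical:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AACGT", "AACGT"),  # revcomp ACGTT is larger
            ("ACGT", "ACGT"),  # self-reverse-complementary
            ("TTTTT", "AAAAA"),
        ],
    )
    def test_examples(self, seq, expected):
        assert ks.canonical_kmer(seq).sequence == expected

    def test_ambiguous_base_rejected(self):
        with pytest.raises(AmbiguousBaseError):
            ks.canonical_kmer("ACNGT")

    @settings(derandomize=True, max_examples=200)
    @given(dna)
    def test_revcomp_invariance(self, seq):
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert ks.canonical_kmer(seq) == ks.canonical_kmer(rc)

    @settings(derandomize=True, max_examples=100)
    @given(dna)
    def test_encode_decode_roundtrip(self, seq):
        assert decode_kmer(encode_kmer(seq), len(seq)) == seq

    def test_revcomp_code_is_involution(self):
        code = encode_kmer("AACGTGA")
        assert revcomp_code(revcomp_code(code, 7), 7) == code


class TestInvertibleHash:
    def test_round_trip_zero(self):
        assert ks.invert_hash(ks.invertible_hash(0)) == 0

    def test_round_trip_random(self):
        rng = np.random.default_rng(0)
        for x in rng.integers(0, 1 << 63, 1000).tolist():
            assert ks.invert_hash(ks.invertible_hash(int(x))) == int(x)

    def test_bijective_on_16bit_domain(self):
        xs = np.arange(1 << 16, dtype=np.uint64)
        hashed = invertible_hash_array(xs)
        assert np.unique(hashed).size == xs.size

    def test_array_matches_scalar(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 1 << 62, 50).astype(np.uint64)
        hv = invertible_hash_array(arr)
        for a, h in zip(arr, hv):
            assert ks.invertible_hash(int(a)) == int(h)


class TestCountKmers:
    def test_window_count(self):
        rng = np.random.default_rng(2)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        table = ks.count_kmers([read])
        assert table.total_mass == 25 - 21 + 1

    def test_additivity(self):
        read = "ACGTACGTACGTACGTACGTACGTA"
        once = ks.count_kmers([read]).to_dict()
        twice = ks.count_kmers([read, read]).to_dict()
        assert twice == {k: 2 * v for k, v in once.items()}

    def test_poly_a(self):
        table = ks.count_kmers(["A" * 25])
        assert table.to_dict() == {0: 5}  # poly-A k-mer encodes to 0

    def test_ambiguous_windows_skipped(self, p5):
        # N at index 10 of a 15-mer poisons windows starting at 6..10
        read = "ACGTACGTAC" + "N" + "GTAC"
        table = ks.count_kmers([read], p5)
        assert table.total_mass == (15 - 5 + 1) - 5

    def test_order_independent(self):
        rng = np.random.default_rng(3)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for _ in range(30)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = ks.count_kmers(reads).to_dict()
        b = ks.count_kmers(shuffled).to_dict()
        assert a == b

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            table = ks.count_kmers([])
        assert table.n_distinct == 0

    def test_fastq_and_gzip_inputs(self, tmp_path):
        rng = np.random.default_rng(4)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(10)]
        fq = tmp_path / "r.fastq"
        ks.simulate.write_fastq(reads, fq)
        import gzip

        fa_gz = tmp_path / "r.fa.gz"
        with gzip.open(fa_gz, "wt") as fh:
            for i, r in enumerate(reads):
                fh.write(f">r{i}\n{r}\n")
        from_list = ks.count_kmers(reads).to_dict()
        assert ks.count_kmers(fq).to_dict() == from_list
        assert ks.count_kmers(fa_gz).to_dict() == from_list


class TestHistogram:
    def test_direct_count(self):
        table = KmerCountTable.from_dict({1: 2, 7: 2, 9: 5}, k=21)
        hist = ks.build_histogram(table)
        assert hist[2] == 2 and hist[5] == 1
        assert hist.total_distinct == 3
        assert hist.total_mass == 9

    def test_empty(self):
        table = KmerCountTable.from_dict({}, k=21)
        hist = ks.build_histogram(table)
        assert hist.total_distinct == 0 and hist.total_mass == 0

    def test_totals_invariant_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            codes = rng.choice(10_000, size=n, replace=False)
            counts = rng.integers(1, 30, size=n)
            table = KmerCountTable.from_dict(
                dict(zip(codes.tolist(), counts.tolist())), k=21
            )
            hist = ks.build_histogram(table)
            assert hist.total_distinct == n
            assert hist.total_mass == int(counts.sum())

    def test_mass_conservation_from_reads(self):
        rng = np.random.default_rng(6)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 80)) for _ in range(20)]
        table = ks.count_kmers(reads)
        hist = ks.build_histogram(table)
        assert hist.total_mass == sum(len(r) - 21 + 1 for r in reads)

    def test_text_round_trip(self, tmp_path):
        hist = ks.KmerHistogram(
            np.array([1, 3, 9], dtype=np.int64), np.array([10, 5, 2], dtype=np.int64)
        )
        path = tmp_path / "hist.txt"
        ks.kmers.write_histogram(hist, path)
        back = ks.kmers.read_histogram(path)
        assert np.array_equal(back.freq, hist.freq)
        assert np.array_equal(back.n_distinct, hist.n_distinct)


def test_sequences_to_codes_matches_scalar_path():
    rng = np.random.default_rng(7)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(5)]
    codes = sorted(sequences_to_codes(seqs, 7).tolist())
    expected = sorted(
        ks.canonical_kmer(s[i : i + 7]).code for s in seqs for i in range(len(s) - 6)
    )
    assert codes == expected
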