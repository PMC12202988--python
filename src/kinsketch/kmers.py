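"""Canonical k-mer encoding, reversible hashing, counting and histograms.

k-mers are packed two bits per base (A=0, C=1, G=2, T=3, so integer
order equals lexicographic order) and stored in canonical form: the
smaller of a k-mer and its reverse complement.  Counting is strand
independent by construction.  All heavy paths are vectorised with numpy
so that a few tens of millions of windows count in seconds.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import os
import warnings
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Kmer",
    "KmerCountTable",
    "KmerHistogram",
    "canonical_kmer",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "invertible_hash",
    "invert_hash",
    "count_kmers",
    "build_histogram",
    "read_histogram",
    "write_histogram",
]

_BASES = "ACGT"

# 256-entry base lookup: ACGT (either case) -> 0..3, everything else -> 4.
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


class AmbiguousBaseError(ValueError):
    """A window contains a non-ACGT character."""


@dataclasses.dataclass(frozen=True)
class Kmer:
    """A canonical k-mer: 2-bit packed code plus its length."""

    code: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.code < 4**self.k:
            raise ValueError("code out of range for k")

    @property
    def sequence(self) -> str:
        return decode_kmer(self.code, self.k)


def encode_kmer(seq: str) -> int:
    """Pack an ACGT string into a 2-bit-per-base integer (A<C<G<T)."""
    code = 0
    for ch in seq.upper():
        b = _BASES.find(ch)
        if b < 0:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in {seq!r}")
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(_BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer (complement is b ^ 3)."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((code & 3) ^ 3)
        code >>= 2
    return rc


def canonical_kmer(seq: str) -> Kmer:
    """Canonical form of ``seq``: min(seq, revcomp(seq)) under A<C<G<T.

    Raises :class:`AmbiguousBaseError` on non-ACGT characters, which
    callers treat as "reject this window".
    """
    k = len(seq)
    code = encode_kmer(seq)
    return Kmer(min(code, revcomp_code(code, k)), k)


# ---------------------------------------------------------------------------
# Reversible 64-bit hash (splitmix64 finalizer).  Only bijectivity matters;
# the constants are conventional.  The inverses of the xorshift steps and of
# the odd multipliers modulo 2**64 give an exact unhash.
# ---------------------------------------------------------------------------

_M1 = 0xBF58476D1CE4E5B9
_M2 = 0x94D049BB133111EB
_M1_INV = pow(_M1, -1, 1 << 64)
_M2_INV = pow(_M2, -1, 1 << 64)
_MASK64 = (1 << 64) - 1


def _xorshift_r(x: int, s: int) -> int:
    return x ^ (x >> s)


def _unxorshift_r(x: int, s: int) -> int:
    # invert y = x ^ (x >> s): iterate r <- y ^ (r >> s) to the fixpoint
    r = x
    for _ in range(64 // s + 1):
        r = x ^ (r >> s)
    return r & _MASK64


def invertible_hash(x: int) -> int:
    """Bijective 64-bit mixer (splitmix64 finalizer)."""
    x &= _MASK64
    x = _xorshift_r(x, 30)
    x = (x * _M1) & _MASK64
    x = _xorshift_r(x, 27)
    x = (x * _M2) & _MASK64
    x = _xorshift_r(x, 31)
    return x


def invert_hash(x: int) -> int:
    """Exact inverse of :func:`invertible_hash`."""
    x &= _MASK64
    x = _unxorshift_r(x, 31)
    x = (x * _M2_INV) & _MASK64
    x = _unxorshift_r(x, 27)
    x = (x * _M1_INV) & _MASK64
    x = _unxorshift_r(x, 30)
    return x


def invertible_hash_array(codes: np.ndarray) -> np.ndarray:
    """Vectorised :func:`invertible_hash` over a uint64 array."""
    x = codes.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(30)
        x *= np.uint64(_M1)
        x ^= x >> np.uint64(27)
        x *= np.uint64(_M2)
        x ^= x >> np.uint64(31)
    return x


# ---------------------------------------------------------------------------
# Vectorised window extraction
# ---------------------------------------------------------------------------


def _codes_from_bytes(vals: np.ndarray, k: int) -> np.ndarray:
    """Canonical codes of every valid k-window of a 0..4 byte array.

    ``vals`` may span several reads joined by sentinel bytes (>= 4);
    any window touching a sentinel or ambiguous base is dropped.
    """
    n = vals.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    bad = (vals >= 4).astype(np.int32)
    cs = np.concatenate([np.zeros(1, np.int32), np.cumsum(bad, dtype=np.int32)])
    valid = (cs[k:] - cs[:-k]) == 0

    v = vals.astype(np.uint64)
    nwin = n - k + 1
    fwd = np.zeros(nwin, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | v[i : i + nwin]
    rc = np.zeros(nwin, dtype=np.uint64)
    tmp = fwd.copy()
    three = np.uint64(3)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | ((tmp & three) ^ three)
        tmp >>= np.uint64(2)
    return np.minimum(fwd, rc)[valid]


def sequences_to_codes(seqs: Sequence[str], k: int) -> np.ndarray:
    """Canonical codes of all valid k-windows of the given sequences."""
    if not seqs:
        return np.empty(0, dtype=np.uint64)
    joined = "\x00".join(seqs)
    vals = _BASE_LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return _codes_from_bytes(vals, k)


# ---------------------------------------------------------------------------
# Read streaming
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _sniff_format(handle: io.TextIOBase) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("input does not look like FASTA or FASTQ")


def iter_sequences(reads) -> Iterator[str]:
    """Yield plain sequence strings from flexible read inputs.

    Accepts a path to FASTA/FASTQ (optionally .gz), an iterable of
    sequence strings, or an iterable of Biopython SeqRecords.
    """
    if isinstance(reads, (str, os.PathLike)):
        with _open_text(reads) as handle:
            fmt = _sniff_format(handle)
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(rec.seq)
                if not seq:
                    raise ValueError(f"malformed record at index {i}: empty sequence")
                yield seq
        return
    for item in reads:
        if isinstance(item, str):
            yield item
        else:
            yield str(item.seq)


def _iter_batches(seq_iter: Iterator[str], batch_bases: int) -> Iterator[list[str]]:
    batch: list[str] = []
    nb = 0
    for seq in seq_iter:
        batch.append(seq)
        nb += len(seq)
        if nb >= batch_bases:
            yield batch
            batch, nb = [], 0
    if batch:
        yield batch


# ---------------------------------------------------------------------------
# Count table and histogram
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KmerCountTable:
    """Counts of canonical k-mers, stored as parallel sorted arrays."""

    codes: np.ndarray  # uint64, ascending
    counts: np.ndarray  # int64, >= 1
    k: int

    @classmethod
    def from_dict(cls, mapping: dict[int, int], k: int) -> "KmerCountTable":
        codes = np.fromiter(mapping.keys(), dtype=np.uint64, count=len(mapping))
        counts = np.fromiter(mapping.values(), dtype=np.int64, count=len(mapping))
        order = np.argsort(codes, kind="stable")
        return cls(codes[order], counts[order], k)

    def to_dict(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(self.codes, self.counts)}

    def get(self, code: int) -> int:
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())


def count_kmers(reads, params=None, *, k: int | None = None) -> KmerCountTable:
    """Count canonical k-mers over every valid window of the reads.

    ``reads`` may be a FASTA/FASTQ(.gz) path or an iterable of sequence
    strings/records.  Windows containing non-ACGT characters are
    skipped.  Each valid window contributes exactly one count.
    """
    from .params import DEFAULT_PARAMS

    if params is None:
        params = DEFAULT_PARAMS
    kk = params.k if k is None else k

    chunks: list[np.ndarray] = []
    n_seqs = 0
    for batch in _iter_batches(iter_sequences(reads), batch_bases=4_000_000):
        n_seqs += len(batch)
        codes = sequences_to_codes(batch, kk)
        if codes.size:
            chunks.append(codes)
    if n_seqs == 0 or not chunks:
        warnings.warn("no k-mers counted: empty input", stacklevel=2)
        return KmerCountTable(
            np.empty(0, np.uint64), np.empty(0, np.int64), kk
        )
    allcodes = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    uniq, counts = np.unique(allcodes, return_counts=True)
    return KmerCountTable(uniq, counts.astype(np.int64), kk)


@dataclasses.dataclass
class KmerHistogram:
    """Number of distinct k-mers per occurrence frequency."""

    freq: np.ndarray  # int64, ascending, >= 1
    n_distinct: np.ndarray  # int64 per frequency

    def __getitem__(self, f: int) -> int:
        i = np.searchsorted(self.freq, f)
        if i < self.freq.size and self.freq[i] == f:
            return int(self.n_distinct[i])
        return 0

    @property
    def total_distinct(self) -> int:
        return int(self.n_distinct.sum())

    @property
    def total_mass(self) -> int:
        return int((self.freq * self.n_distinct).sum())

    @property
    def max_freq(self) -> int:
        return int(self.freq[-1]) if self.freq.size else 0

    def dense(self, max_f: int) -> np.ndarray:
        """Dense [0..max_f] vector of n_distinct (index 0 unused)."""
        out = np.zeros(max_f + 1, dtype=np.int64)
        sel = self.freq <= max_f
        out[self.freq[sel]] = self.n_distinct[sel]
        return out

    @classmethod
    def from_dict(cls, mapping: dict[int, int]) -> "KmerHistogram":
        freq = np.sort(np.fromiter(mapping.keys(), dtype=np.int64, count=len(mapping)))
        nd = np.array([mapping[int(f)] for f in freq], dtype=np.int64)
        return cls(freq, nd)


def build_histogram(table: KmerCountTable, params=None) -> KmerHistogram:
    """Histogram of k-mer abundances: freq -> number of distinct k-mers."""
    if table.counts.size == 0:
        return KmerHistogram(np.empty(0, np.int64), np.empty(0, np.int64))
    freq, nd = np.unique(table.counts, return_counts=True)
    return KmerHistogram(freq.astype(np.int64), nd.astype(np.int64))


def write_histogram(hist: KmerHistogram, path: str | os.PathLike) -> None:
    """Two-column text layout: ``frequency  n_distinct`` per row."""
    with open(path, "w") as fh:
        for f, n in zip(hist.freq, hist.n_distinct):
            fh.write(f"{int(f)}\t{int(n)}\n")


def read_histogram(path: str | os.PathLike) -> KmerHistogram:
    freqs: list[int] = []
    nds: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f, n = line.split()
            freqs.append(int(f))
            nds.append(int(n))
    order = np.argsort(freqs)
    return KmerHistogram(
        np.asarray(freqs, dtype=np.int64)[order],
        np.asarray(nds, dtype=np.int64)[order],
    )
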