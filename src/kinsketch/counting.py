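"""Stage 2: streaming k-mer counting of a query sample against a sketch.

The sketch's canonical k-mers are indexed in a hash table keyed by a
reversible 64-bit hash of the packed code (the hash is a bijection, so
the key can always be mapped back to its k-mer).  Query reads are
decomposed into canonical k-mers; every window matching a sketch entry
increments that entry's slot.  Per site, the slot vectors are reduced
to two scalars per allele: the modal count (robust against repetitive
or error-inflated slots; used by the relatedness score) and the maximum
count (sensitive at very low coverage; used by the likelihood score).
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Iterator, Sequence

import numpy as np

from . import kmers as km
from .params import DEFAULT_PARAMS, Params
from .sketch import VariantSketch

__all__ = [
    "SketchIndex",
    "SiteCounts",
    "index_sketch",
    "count_sample",
    "site_allele_count",
]


@dataclasses.dataclass
class SketchIndex:
    """Vectorised lookup: hashed canonical code -> (site, allele, slot)."""

    hashed: np.ndarray  # uint64, ascending (reversible hash of codes)
    site_idx: np.ndarray  # int32 per entry
    allele: np.ndarray  # uint8: 0 = ref, 1 = alt
    slot: np.ndarray  # int32 position within the allele's k-mer list
    site_ids: list[str]
    n_slots_ref: np.ndarray  # per site
    n_slots_alt: np.ndarray
    k: int

    def __len__(self) -> int:
        return int(self.hashed.size)

    def lookup(self, code: int) -> tuple[str, str, int] | None:
        """Resolve one canonical code (None on miss)."""
        h = km.invertible_hash(code)
        i = int(np.searchsorted(self.hashed, np.uint64(h)))
        if i < self.hashed.size and self.hashed[i] == np.uint64(h):
            return (
                self.site_ids[int(self.site_idx[i])],
                "ref" if self.allele[i] == 0 else "alt",
                int(self.slot[i]),
            )
        return None


def index_sketch(sketch: VariantSketch) -> SketchIndex:
    codes: list[int] = []
    site_idx: list[int] = []
    allele: list[int] = []
    slot: list[int] = []
    for si, site in enumerate(sketch.sites):
        for al, kmers in ((0, site.ref_kmers), (1, site.alt_kmers)):
            for sl, code in enumerate(kmers):
                codes.append(code)
                site_idx.append(si)
                allele.append(al)
                slot.append(sl)
    hashed = km.invertible_hash_array(np.asarray(codes, dtype=np.uint64))
    order = np.argsort(hashed, kind="stable")
    return SketchIndex(
        hashed=hashed[order],
        site_idx=np.asarray(site_idx, dtype=np.int32)[order],
        allele=np.asarray(allele, dtype=np.uint8)[order],
        slot=np.asarray(slot, dtype=np.int32)[order],
        site_ids=[s.site_id for s in sketch.sites],
        n_slots_ref=np.asarray([len(s.ref_kmers) for s in sketch.sites], np.int32),
        n_slots_alt=np.asarray([len(s.alt_kmers) for s in sketch.sites], np.int32),
        k=sketch.k,
    )


def site_allele_count(slot_counts: Sequence[int]) -> int:
    """Modal slot count; ties break toward the smaller value; [] -> 0."""
    arr = np.asarray(slot_counts, dtype=np.int64)
    if arr.size == 0:
        return 0
    values, freqs = np.unique(arr, return_counts=True)  # values ascending
    return int(values[np.argmax(freqs)])  # argmax takes first = smallest


@dataclasses.dataclass
class SiteCounts:
    """Per-site allele count summaries for one query sample.

    ``ref``/``alt`` are the modal slot counts, ``ref_max``/``alt_max``
    the maxima; both reductions coincide for count-level simulations
    where each site carries a single (ref, alt) pair.
    """

    site_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray
    ref_max: np.ndarray
    alt_max: np.ndarray
    sample: str = "query"
    n_reads_processed: int = 0
    n_bases_processed: int = 0
    early_stopped: bool = False
    ref_slots: list[np.ndarray] | None = None
    alt_slots: list[np.ndarray] | None = None

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @classmethod
    def from_scalars(
        cls, ref: np.ndarray, alt: np.ndarray, sample: str = "sim",
        site_ids: list[str] | None = None,
    ) -> "SiteCounts":
        ref = np.asarray(ref, dtype=np.int64)
        alt = np.asarray(alt, dtype=np.int64)
        if site_ids is None:
            site_ids = [f"{sample}.{i:06d}" for i in range(ref.size)]
        return cls(
            site_ids=site_ids, ref=ref, alt=alt,
            ref_max=ref.copy(), alt_max=alt.copy(), sample=sample,
        )

    def write_tsv(self, path: str | os.PathLike, long: bool = False) -> None:
        with open(path, "w") as fh:
            if long and self.ref_slots is not None:
                fh.write("site_id\tref_count\talt_count\tref_slots\talt_slots\n")
                for i, sid in enumerate(self.site_ids):
                    rs = ",".join(map(str, self.ref_slots[i]))
                    as_ = ",".join(map(str, self.alt_slots[i]))
                    fh.write(f"{sid}\t{self.ref[i]}\t{self.alt[i]}\t{rs}\t{as_}\n")
            else:
                fh.write("site_id\tref_count\talt_count\n")
                for i, sid in enumerate(self.site_ids):
                    fh.write(f"{sid}\t{self.ref[i]}\t{self.alt[i]}\n")


def _reduce_slots(
    index: SketchIndex, flat: np.ndarray, sample: str,
    n_reads: int, n_bases: int, early: bool, keep_slots: bool,
) -> SiteCounts:
    n_sites = len(index.site_ids)
    ref_mode = np.zeros(n_sites, dtype=np.int64)
    alt_mode = np.zeros(n_sites, dtype=np.int64)
    ref_max = np.zeros(n_sites, dtype=np.int64)
    alt_max = np.zeros(n_sites, dtype=np.int64)
    ref_slots: list[np.ndarray] = []
    alt_slots: list[np.ndarray] = []

    # regroup flat slot counts per (site, allele) in site order
    order = np.lexsort((index.slot, index.allele, index.site_idx))
    sidx = index.site_idx[order]
    sall = index.allele[order]
    vals = flat[order]
    key = sidx.astype(np.int64) * 2 + sall
    boundaries = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [key.size]])
    per_site: dict[int, dict[int, np.ndarray]] = {}
    for s, e in zip(starts, ends):
        per_site.setdefault(int(sidx[s]), {})[int(sall[s])] = vals[s:e]
    empty = np.empty(0, dtype=np.int64)
    for si in range(n_sites):
        slots = per_site.get(si, {})
        rv = slots.get(0, empty)
        av = slots.get(1, empty)
        ref_mode[si] = site_allele_count(rv)
        alt_mode[si] = site_allele_count(av)
        ref_max[si] = int(rv.max()) if rv.size else 0
        alt_max[si] = int(av.max()) if av.size else 0
        if keep_slots:
            ref_slots.append(rv)
            alt_slots.append(av)
    return SiteCounts(
        site_ids=list(index.site_ids),
        ref=ref_mode, alt=alt_mode, ref_max=ref_max, alt_max=alt_max,
        sample=sample, n_reads_processed=n_reads, n_bases_processed=n_bases,
        early_stopped=early,
        ref_slots=ref_slots if keep_slots else None,
        alt_slots=alt_slots if keep_slots else None,
    )


def count_sample(
    reads,
    index: SketchIndex,
    params: Params = DEFAULT_PARAMS,
    expected_cov: float | None = None,
    sample: str = "query",
    keep_slots: bool = False,
) -> SiteCounts:
    """Count sketch k-mers in a query sample.

    Every valid window matching a sketch k-mer increments its slot.
    With ``expected_cov`` set, reading stops once the mean count over
    all sketch slots reaches that value (checked every
    ``early_stop_check_reads`` reads), making counts read-order
    dependent only through the stopping point.
    """
    k = index.k
    flat = np.zeros(len(index), dtype=np.int64)
    n_reads = 0
    n_bases = 0
    early = False
    check_every = params.early_stop_check_reads
    next_check = check_every

    batch: list[str] = []
    batch_bases = 0

    def flush(batch: list[str]) -> None:
        if index.hashed.size == 0:
            return
        codes = km.sequences_to_codes(batch, k)
        if codes.size == 0:
            return
        hashed = km.invertible_hash_array(codes)
        pos = np.searchsorted(index.hashed, hashed)
        pos[pos >= index.hashed.size] = 0
        hit = index.hashed[pos] == hashed
        np.add.at(flat, pos[hit], 1)

    seq_iter = km.iter_sequences(reads)
    for seq in seq_iter:
        batch.append(seq)
        batch_bases += len(seq)
        n_reads += 1
        n_bases += len(seq)
        if batch_bases >= 2_000_000 or n_reads >= next_check:
            flush(batch)
            batch, batch_bases = [], 0
            if expected_cov is not None and n_reads >= next_check:
                next_check += check_every
                if flat.size and flat.mean() >= expected_cov:
                    early = True
                    break
    if batch and not early:
        flush(batch)
    if n_reads == 0:
        warnings.warn("empty input: all counts are zero", stacklevel=2)
    return _reduce_slots(index, flat, sample, n_reads, n_bases, early, keep_slots)
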