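"""Stage 1: reference-free calling of isolated heterozygous SNPs.

Heterozygous-region k-mers form the vertices of a graph whose edges are
k-mer pairs differing only at the middle base (potential SNPs).  Each
edge is weighted by its support length: how far the shared flanks of
the two alleles can be extended while every shifted window pair stays
inside the heterozygous set (max k).  A maximum-weight matching picks a
consistent set of SNPs, and only full-support (== k) calls survive,
which is what keeps precision high at low coverage.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import kmers as km
from .kmers import KmerCountTable, KmerHistogram
from .params import DEFAULT_PARAMS, Params
from .spectrum import (
    GenomeProfile,
    HetRegion,
    Peak,
    detect_peaks,
    fit_two_nb,
    het_region,
    select_het_peak,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HetKmerSet",
    "CandidatePair",
    "SnpCall",
    "Stage1Result",
    "extract_het_kmers",
    "find_candidate_pairs",
    "support_length",
    "max_weight_matching",
    "call_snps",
    "run_stage1",
]


@dataclasses.dataclass
class HetKmerSet:
    """Canonical k-mer codes whose counts fall inside the het region."""

    codes: np.ndarray  # uint64, ascending
    k: int

    def __post_init__(self) -> None:
        self._set = {int(c) for c in self.codes}

    def __contains__(self, code: int) -> bool:
        return code in self._set

    def __len__(self) -> int:
        return len(self._set)

    @classmethod
    def from_codes(cls, codes: Iterable[int], k: int) -> "HetKmerSet":
        arr = np.array(sorted(set(int(c) for c in codes)), dtype=np.uint64)
        return cls(arr, k)


@dataclasses.dataclass
class CandidatePair:
    """Two heterozygous k-mers differing only at the middle base.

    ``kmer_a < kmer_b`` are canonical codes; ``oriented_a/oriented_b``
    is the orientation pair in which the two differ at exactly the
    middle position, fixed deterministically (smallest oriented_a).
    """

    kmer_a: int
    kmer_b: int
    oriented_a: int
    oriented_b: int
    support: int = 0


@dataclasses.dataclass
class SnpCall:
    """An isolated heterozygous SNP: two 2k-1 contexts differing at the
    centre, plus the support length of the underlying k-mer pair."""

    site_id: int
    ref_context: str
    alt_context: str
    support: int


def extract_het_kmers(table: KmerCountTable, region: HetRegion) -> HetKmerSet:
    """Select exactly the k-mers with count in [region.lo, region.hi]."""
    sel = (table.counts >= region.lo) & (table.counts <= region.hi)
    codes = table.codes[sel]
    if codes.size == 0:
        warnings.warn(
            "no heterozygous k-mers; check coverage/region", stacklevel=2
        )
    return HetKmerSet(codes.copy(), table.k)


def _masked_and_middle(codes: np.ndarray, k: int):
    """Drop the middle base of each oriented code; return (mask, middle)."""
    mid_shift = np.uint64(2 * (k // 2))
    low_mask = np.uint64((1 << (2 * (k // 2))) - 1)
    middle = (codes >> mid_shift) & np.uint64(3)
    masked = ((codes >> (mid_shift + np.uint64(2))) << mid_shift) | (codes & low_mask)
    return masked, middle


def _revcomp_array(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    three = np.uint64(3)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | ((tmp & three) ^ three)
        tmp >>= np.uint64(2)
    return rc


def find_candidate_pairs(
    het: HetKmerSet, params: Params = DEFAULT_PARAMS
) -> list[CandidatePair]:
    """Every unordered pair of het k-mers that, in some orientation,
    differ at exactly the middle position.

    Both orientations of each canonical k-mer are bucketed by their
    middle-base-masked form; any two distinct canonical k-mers sharing
    a bucket form a pair.  Output is deduplicated and sorted by code
    pair, with the oriented representation fixed to the presentation
    whose ``oriented_a`` is smallest.
    """
    k = het.k
    canon = het.codes
    n = canon.size
    if n < 2:
        return []
    rc = _revcomp_array(canon, k)
    oriented = np.concatenate([canon, rc])
    owner = np.concatenate([np.arange(n), np.arange(n)])
    masked, _ = _masked_and_middle(oriented, k)

    order = np.argsort(masked, kind="stable")
    ms = masked[order]
    boundaries = np.flatnonzero(ms[1:] != ms[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [ms.size]])

    best: dict[tuple[int, int], tuple[int, int]] = {}
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        idx = order[s:e]
        group_owner = owner[idx]
        group_oriented = oriented[idx]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                oi, oj = int(group_owner[i]), int(group_owner[j])
                if oi == oj:
                    continue
                ca, cb = int(canon[oi]), int(canon[oj])
                a, b = int(group_oriented[i]), int(group_oriented[j])
                if cb < ca:
                    ca, cb = cb, ca
                if b < a:
                    a, b = b, a
                key = (ca, cb)
                if key not in best or (a, b) < best[key]:
                    best[key] = (a, b)
    pairs = [
        CandidatePair(kmer_a=ka, kmer_b=kb, oriented_a=oa, oriented_b=ob)
        for (ka, kb), (oa, ob) in sorted(best.items())
    ]
    return pairs


def _extend(
    pair: CandidatePair, het: HetKmerSet, k: int
) -> tuple[int, list[int], list[int]]:
    """Walk the shared flanks outwards; return (support, left, right).

    A step succeeds iff exactly one base keeps both shifted allele
    windows inside the het set; an ambiguous step (more than one base
    succeeds) stops the walk in that direction to avoid chimeric
    contexts.  ``left`` holds the prepended bases outermost-last,
    ``right`` the appended bases in order.
    """
    mid = k // 2
    mask = (1 << (2 * k)) - 1
    top = 2 * (k - 1)

    def canon(f: int, r: int) -> int:
        return f if f < r else r

    states = {}
    for name, code in (("a", pair.oriented_a), ("b", pair.oriented_b)):
        states[name] = (code, km.revcomp_code(code, k))

    def walk(direction: str) -> list[int]:
        fa, ra = states["a"]
        fb, rb = states["b"]
        out: list[int] = []
        for _ in range(mid):
            hits = []
            for c in range(4):
                if direction == "left":
                    nfa = (c << top) | (fa >> 2)
                    nra = ((ra << 2) | (c ^ 3)) & mask
                    nfb = (c << top) | (fb >> 2)
                    nrb = ((rb << 2) | (c ^ 3)) & mask
                else:
                    nfa = ((fa << 2) | c) & mask
                    nra = ((c ^ 3) << top) | (ra >> 2)
                    nfb = ((fb << 2) | c) & mask
                    nrb = ((c ^ 3) << top) | (rb >> 2)
                if canon(nfa, nra) in het and canon(nfb, nrb) in het:
                    hits.append((c, nfa, nra, nfb, nrb))
            if len(hits) != 1:
                break
            c, fa, ra, fb, rb = hits[0]
            out.append(c)
        return out

    left = walk("left")
    right = walk("right")
    support = min(k, 1 + len(left) + len(right))
    return support, left, right


def support_length(
    pair: CandidatePair, het: HetKmerSet, params: Params = DEFAULT_PARAMS
) -> int:
    """Support length of a candidate pair (1..k)."""
    support, _, _ = _extend(pair, het, het.k)
    return support


def _greedy_matching(edges: list[tuple[int, int, int, int]]) -> set[int]:
    """Deterministic greedy fallback: by (-weight, kmer_a, kmer_b)."""
    chosen: set[int] = set()
    used: set[int] = set()
    for w, a, b, i in sorted(
        ((w, a, b, i) for a, b, w, i in edges), key=lambda t: (-t[0], t[1], t[2])
    ):
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        chosen.add(i)
    return chosen


def max_weight_matching(
    pairs: Sequence[CandidatePair], params: Params = DEFAULT_PARAMS
) -> list[CandidatePair]:
    """Maximum-weight matching over the candidate-pair graph.

    Vertices are k-mers, edge weights are support lengths.  Connected
    components are solved independently with the exact blossom
    algorithm; ties between equal-weight matchings are broken toward
    lexicographically smaller code pairs by a rank penalty that cannot
    change the optimal total weight.  Components larger than
    ``matching_exact_max_nodes`` fall back to deterministic greedy
    matching.
    """
    if not pairs:
        return []
    g = nx.Graph()
    for i, p in enumerate(pairs):
        # parallel edges cannot occur: pairs are unique on (kmer_a, kmer_b)
        g.add_edge(p.kmer_a, p.kmer_b, weight=p.support, index=i)

    selected: set[int] = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        edges = [
            (a, b, d["weight"], d["index"])
            for a, b, d in sub.edges(data=True)
        ]
        if len(comp) > params.matching_exact_max_nodes:
            selected |= _greedy_matching(edges)
            continue
        edges_sorted = sorted(edges, key=lambda t: (min(t[0], t[1]), max(t[0], t[1])))
        m = len(edges_sorted)
        big = m * m + 1
        h = nx.Graph()
        for rank, (a, b, w, i) in enumerate(edges_sorted):
            h.add_edge(a, b, weight=w * big - rank, index=i)
        mate = nx.max_weight_matching(h, maxcardinality=False)
        for a, b in mate:
            selected.add(h.edges[a, b]["index"])
    return [pairs[i] for i in sorted(selected)]


@dataclasses.dataclass
class Stage1Result:
    """Everything stage 1 produced, for reporting and serialization."""

    calls: list[SnpCall]
    histogram: KmerHistogram
    peaks: list[Peak]
    region: HetRegion
    profile: GenomeProfile
    n_het_kmers: int
    n_candidate_pairs: int
    n_matched: int


def _contexts_from_pair(
    pair: CandidatePair, left: list[int], right: list[int], k: int
) -> tuple[str, str]:
    prefix = "".join("ACGT"[c] for c in reversed(left))
    suffix = "".join("ACGT"[c] for c in right)
    ctx_a = prefix + km.decode_kmer(pair.oriented_a, k) + suffix
    ctx_b = prefix + km.decode_kmer(pair.oriented_b, k) + suffix
    return ctx_a, ctx_b


def run_stage1(
    reads,
    params: Params = DEFAULT_PARAMS,
    high_het: bool = False,
    table: KmerCountTable | None = None,
) -> Stage1Result:
    """Full stage-1 pipeline: count -> spectrum -> region -> pairs ->
    support -> matching -> full-support filter -> contexts.

    ``table`` may be supplied to skip recounting (e.g. in tests).
    Raises :class:`kinsketch.spectrum.NoPeakError` when the spectrum
    shows no usable peak and ``RuntimeError`` when no SNP survives.
    """
    k = params.k
    if table is None:
        table = km.count_kmers(reads, params)
    hist = km.build_histogram(table, params)
    peaks = detect_peaks(hist, params)
    het_peak = select_het_peak(peaks, high_het, params)
    region = het_region(het_peak, params)
    logger.info(
        "spectrum: peaks=%s het_peak=%d region=[%d, %d]",
        [p.freq for p in peaks], het_peak, region.lo, region.hi,
    )
    profile = fit_two_nb(hist, het_peak, params)

    het = extract_het_kmers(table, region)
    logger.info("het k-mers: %d", len(het))
    pairs = find_candidate_pairs(het, params)

    extensions: dict[tuple[int, int], tuple[int, list[int], list[int]]] = {}
    for p in pairs:
        support, left, right = _extend(p, het, k)
        p.support = support
        extensions[(p.kmer_a, p.kmer_b)] = (support, left, right)

    matched = max_weight_matching(pairs, params)
    required = params.full_support
    calls: list[SnpCall] = []
    for p in matched:
        support, left, right = extensions[(p.kmer_a, p.kmer_b)]
        if support != required:
            continue
        ctx_a, ctx_b = _contexts_from_pair(p, left, right, k)
        ref, alt = (ctx_a, ctx_b) if ctx_a < ctx_b else (ctx_b, ctx_a)
        calls.append(SnpCall(site_id=-1, ref_context=ref, alt_context=alt, support=support))

    calls.sort(key=lambda c: c.ref_context)
    for i, c in enumerate(calls):
        c.site_id = i
    if not calls:
        raise RuntimeError(
            "no SNP calls passed the support filter; "
            "check coverage and the heterozygous region"
        )
    if len(calls) < params.min_sketch_sites:
        warnings.warn(
            f"only {len(calls)} SNP sites called "
            f"(< {params.min_sketch_sites}); identity checks on very "
            "low-coverage or high-error samples may be unreliable",
            stacklevel=2,
        )
    return Stage1Result(
        calls=calls,
        histogram=hist,
        peaks=peaks,
        region=region,
        profile=profile,
        n_het_kmers=len(het),
        n_candidate_pairs=len(pairs),
        n_matched=len(matched),
    )


def call_snps(
    reads, params: Params = DEFAULT_PARAMS, high_het: bool = False, **kwargs
) -> list[SnpCall]:
    """Stage-1 orchestration; returns the filtered SNP calls."""
    return run_stage1(reads, params, high_het, **kwargs).calls
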