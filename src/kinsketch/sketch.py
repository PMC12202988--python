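"""Variant sketches: per-site ref/alt k-mer sets with global dedup.

Each called SNP contributes the k sliding windows of its ref context
and the k windows of its alt context, all canonicalized.  Any canonical
k-mer that occurs more than once anywhere in a sketch (within a site,
across sites, across alleles, or across merged individuals) is removed
from every occurrence: a shared k-mer cannot attribute query counts to
one site/allele, so keeping any copy would break the independence of
sites.  Sites left without at least one k-mer per allele are dropped.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from collections import Counter
from typing import Iterable, Sequence

from . import kmers as km
from .calling import SnpCall
from .params import DEFAULT_PARAMS, Params

__all__ = [
    "SketchSite",
    "VariantSketch",
    "build_sketch",
    "write_sketch",
    "read_sketch",
    "merge_sketches",
]


@dataclasses.dataclass
class SketchSite:
    site_id: str
    ref_kmers: list[int]
    alt_kmers: list[int]


@dataclasses.dataclass
class VariantSketch:
    """Deduplicated per-site ref/alt canonical k-mer sets."""

    sites: list[SketchSite]
    k: int
    individuals: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def all_kmers(self) -> list[int]:
        out: list[int] = []
        for s in self.sites:
            out.extend(s.ref_kmers)
            out.extend(s.alt_kmers)
        return out

    def validate(self) -> None:
        kmers = self.all_kmers()
        if len(kmers) != len(set(kmers)):
            raise ValueError("corrupt sketch: duplicate k-mer")
        for s in self.sites:
            if not s.ref_kmers or not s.alt_kmers:
                raise ValueError(f"corrupt sketch: site {s.site_id} lacks an allele")


def _context_kmers(context: str, k: int) -> list[int]:
    return [km.canonical_kmer(context[i : i + k]).code for i in range(len(context) - k + 1)]


def _dedup_sites(raw_sites: list[SketchSite], individuals: list[str], k: int) -> VariantSketch:
    counts = Counter()
    for s in raw_sites:
        counts.update(s.ref_kmers)
        counts.update(s.alt_kmers)
    kept_sites: list[SketchSite] = []
    n_dropped = 0
    for s in raw_sites:
        ref = [c for c in s.ref_kmers if counts[c] == 1]
        alt = [c for c in s.alt_kmers if counts[c] == 1]
        if ref and alt:
            kept_sites.append(SketchSite(s.site_id, ref, alt))
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sites left without a ref or alt k-mer "
            "after duplicate removal",
            stacklevel=3,
        )
    kept_sites.sort(key=lambda s: s.site_id)
    return VariantSketch(sites=kept_sites, k=k, individuals=individuals)


def build_sketch(
    snps: Sequence[SnpCall],
    params: Params = DEFAULT_PARAMS,
    individual: str = "sample",
) -> VariantSketch:
    """Build a sketch from SNP calls (2k-1 contexts, variant centred)."""
    if not snps:
        raise ValueError("cannot build a sketch from zero SNP calls")
    k = params.k
    raw: list[SketchSite] = []
    for call in snps:
        if len(call.ref_context) != 2 * k - 1 or len(call.alt_context) != 2 * k - 1:
            raise ValueError(
                f"site {call.site_id}: contexts must have length {2 * k - 1}"
            )
        raw.append(
            SketchSite(
                site_id=f"{individual}.{call.site_id:06d}",
                ref_kmers=_context_kmers(call.ref_context, k),
                alt_kmers=_context_kmers(call.alt_context, k),
            )
        )
    return _dedup_sites(raw, [individual], k)


def write_sketch(sketch: VariantSketch, path: str | os.PathLike) -> None:
    """Serialize to the sketch FASTA dialect.

    One record per retained k-mer, header ``>site{ID}|{allele}|{index}``
    and a k-length sequence; the file is self-validating (uniqueness is
    re-checked on read).
    """
    if not sketch.sites:
        raise ValueError("refusing to write an empty sketch")
    sketch.validate()
    with open(path, "w") as fh:
        for site in sketch.sites:
            for allele, codes in (("ref", site.ref_kmers), ("alt", site.alt_kmers)):
                for idx, code in enumerate(codes):
                    fh.write(
                        f">site{site.site_id}|{allele}|{idx}\n"
                        f"{km.decode_kmer(code, sketch.k)}\n"
                    )


def write_sketch_sidecar(sketch: VariantSketch, path: str | os.PathLike) -> None:
    """TSV sidecar: site_id, n_ref_kmers, n_alt_kmers, individual."""
    with open(path, "w") as fh:
        fh.write("site_id\tn_ref_kmers\tn_alt_kmers\tindividual\n")
        for s in sketch.sites:
            indiv = s.site_id.rsplit(".", 1)[0]
            fh.write(f"{s.site_id}\t{len(s.ref_kmers)}\t{len(s.alt_kmers)}\t{indiv}\n")


def read_sketch(path: str | os.PathLike, params: Params | None = None) -> VariantSketch:
    """Parse and validate a sketch FASTA written by :func:`write_sketch`."""
    sites: dict[str, SketchSite] = {}
    k: int | None = None
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:]
                continue
            if header is None or not header.startswith("site"):
                raise ValueError("corrupt sketch: malformed FASTA structure")
            try:
                ident, allele, _idx = header[len("site") :].split("|")
            except ValueError as exc:
                raise ValueError(f"corrupt sketch: bad header {header!r}") from exc
            if k is None:
                k = len(line)
            if len(line) != k:
                raise ValueError(
                    f"corrupt sketch: k-mer length {len(line)} != {k}"
                )
            if params is not None and k != params.k:
                raise ValueError(f"sketch has k={k}, expected k={params.k}")
            code = km.canonical_kmer(line).code
            site = sites.setdefault(ident, SketchSite(ident, [], []))
            (site.ref_kmers if allele == "ref" else site.alt_kmers).append(code)
            header = None
    if k is None:
        raise ValueError("corrupt sketch: no records")
    individuals = sorted({s.rsplit(".", 1)[0] for s in sites})
    sketch = VariantSketch(
        sites=sorted(sites.values(), key=lambda s: s.site_id),
        k=k,
        individuals=individuals,
    )
    sketch.validate()
    return sketch


def merge_sketches(sketches: Sequence[VariantSketch]) -> VariantSketch:
    """Union of sketches with the same global dedup rule re-applied."""
    if not sketches:
        raise ValueError("nothing to merge")
    ks = {s.k for s in sketches}
    if len(ks) != 1:
        raise ValueError(f"cannot merge sketches with mixed k: {sorted(ks)}")
    k = ks.pop()
    raw = [
        SketchSite(s.site_id, list(s.ref_kmers), list(s.alt_kmers))
        for sk in sketches
        for s in sk.sites
    ]
    individuals = sorted({i for sk in sketches for i in sk.individuals})
    return _dedup_sites(raw, individuals, k)
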