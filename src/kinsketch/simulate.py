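"""Synthetic data: count-level score simulations and a diploid
genome/read simulator for end-to-end tests.

Two generators live here.  The count-level simulator reproduces the
score-calibration protocol: a sketch of 200k heterozygous sites, site
depth d ~ Poisson(coverage), and, for an identical pair, a binomial
allele split with P = 0.5; for a first-degree pair half the sites are
binomial and the other half place the full depth on one random allele
(the relative is homozygous there).  The sequence-level simulator
plants isolated heterozygous SNPs (minimum spacing 2k-1 so every
41-mer context is variant-free except at its centre) on a random or
supplied genome and samples substitution-error reads from both
haplotypes.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .counting import SiteCounts
from .params import DEFAULT_PARAMS, Params
from .scoring import likelihood_score

__all__ = [
    "SimConfig",
    "DEFAULT_COVERAGES",
    "simulate_site_counts",
    "run_score_study",
    "DiploidTruth",
    "simulate_diploid",
    "simulate_reads",
    "write_fastq",
]

DEFAULT_COVERAGES = (0.1, 0.2, 0.3, 0.5, 1, 2, 3, 4, 6, 8, 10, 20, 30)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class SimConfig:
    """Stated world of the count-level simulation."""

    n_sites: int = 200_000
    coverage: float = 30.0
    relationship: str = "identical"  # identical | first_degree
    p_het: float = 0.5
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relationship not in ("identical", "first_degree"):
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


def _simulate_counts_matrix(
    cfg: SimConfig, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(reps, n_sites) ref and alt count matrices under the protocol."""
    n = cfg.n_sites
    d = rng.poisson(cfg.coverage, size=(reps, n))
    ref = rng.binomial(d, cfg.p_het)
    alt = d - ref
    if cfg.relationship == "first_degree":
        # an independent random half of the sites is homozygous in the
        # relative: full depth on one uniformly chosen allele
        hom = rng.random(size=(reps, n)) < 0.5
        to_ref = rng.random(size=(reps, n)) < 0.5
        ref = np.where(hom, np.where(to_ref, d, 0), ref)
        alt = np.where(hom, np.where(to_ref, 0, d), alt)
    return ref, alt


def simulate_site_counts(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SiteCounts:
    """One simulated query sample's per-site (ref, alt) counts."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref, alt = _simulate_counts_matrix(cfg, 1, rng)
    return SiteCounts.from_scalars(
        ref[0], alt[0], sample=f"sim-{cfg.relationship}"
    )


def run_score_study(
    coverages: Sequence[float] = DEFAULT_COVERAGES,
    relationships: Sequence[str] = ("identical", "first_degree"),
    n_sites: int = 200_000,
    reps: int = 1000,
    seed: int = 0,
    params: Params = DEFAULT_PARAMS,
    rep_chunk: int = 20,
) -> pd.DataFrame:
    """Replicated likelihood-score study over a coverage grid.

    Each (coverage, relationship) cell is simulated ``reps`` times and
    scored; the mean, 1st and 99th percentiles across replicates are
    recorded, which is what calibrates the identity decision bound.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cov in coverages:
        for rel in relationships:
            cfg = SimConfig(
                n_sites=n_sites, coverage=float(cov), relationship=rel, reps=reps
            )
            scores = np.empty(reps)
            n_eff = np.empty(reps)
            done = 0
            while done < reps:
                m = min(rep_chunk, reps - done)
                ref, alt = _simulate_counts_matrix(cfg, m, rng)
                for i in range(m):
                    sc = SiteCounts.from_scalars(ref[i], alt[i])
                    res = likelihood_score(sc, params)
                    scores[done + i] = res.lambda_bar
                    n_eff[done + i] = res.n_effective
                done += m
            finite = scores[np.isfinite(scores)]
            if finite.size == 0:
                mean = p1 = p99 = float("nan")
            else:
                mean = float(finite.mean())
                p1 = float(np.percentile(finite, 1))
                p99 = float(np.percentile(finite, 99))
            rows.append(
                {
                    "coverage": float(cov),
                    "relationship": rel,
                    "reps": reps,
                    "mean": mean,
                    "p1": p1,
                    "p99": p99,
                    "mean_effective_sites": float(np.mean(n_eff)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence-level simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TruthSnp:
    position: int
    ref_base: str
    alt_base: str
    ref_context: str
    alt_context: str


@dataclasses.dataclass
class DiploidTruth:
    hap1: str
    hap2: str
    truth: list[TruthSnp]

    @property
    def genome_len(self) -> int:
        return len(self.hap1)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def simulate_diploid(
    genome_len: int,
    het_rate: float,
    seed: int = 0,
    params: Params = DEFAULT_PARAMS,
    genome: np.ndarray | None = None,
) -> DiploidTruth:
    """Plant isolated heterozygous SNPs on a diploid genome.

    SNP positions follow a renewal process with gaps
    ``(2k-1) + Geometric`` whose mean is 1/het_rate, guaranteeing the
    minimum spacing that makes every SNP isolated.  ``genome`` may be
    supplied (0..3 byte array) so several individuals can share one
    species backbone; otherwise a uniform random genome is drawn.
    hap1 carries the ref allele and hap2 the alt allele at every site.
    """
    k = params.k
    spacing = 2 * k - 1
    if genome_len < 10 * spacing:
        raise ValueError(f"genome_len must be >= {10 * spacing}")
    if het_rate < 0 or het_rate > 0.05:
        raise ValueError("het_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    if genome is None:
        genome = rng.integers(0, 4, size=genome_len, dtype=np.uint8)
    else:
        genome = np.asarray(genome, dtype=np.uint8)
        if genome.size != genome_len:
            raise ValueError("supplied genome length mismatch")

    hap1 = genome.copy()
    hap2 = genome.copy()
    truth: list[TruthSnp] = []
    if het_rate > 0:
        mean_gap = 1.0 / het_rate
        if mean_gap <= spacing:
            raise ValueError(
                f"het_rate {het_rate} infeasible with minimum spacing {spacing}"
            )
        p_geom = 1.0 / (mean_gap - spacing + 1.0)  # geometric on {1, 2, ...}
        mid = k - 1  # centre offset within the 2k-1 context
        positions: list[int] = []
        pos = mid - spacing  # so the first gap can land from mid onwards
        while True:
            pos += spacing + int(rng.geometric(p_geom)) - 1
            if pos > genome_len - 1 - mid:
                break
            positions.append(pos)
        for pos in positions:
            ref_b = int(genome[pos])
            alt_b = (ref_b + int(rng.integers(1, 4))) % 4
            hap2[pos] = alt_b
            ctx = genome[pos - mid : pos + mid + 1]
            ref_ctx = _decode(ctx)
            alt_ctx_arr = ctx.copy()
            alt_ctx_arr[mid] = alt_b
            truth.append(
                TruthSnp(
                    position=pos,
                    ref_base="ACGT"[ref_b],
                    alt_base="ACGT"[alt_b],
                    ref_context=ref_ctx,
                    alt_context=_decode(alt_ctx_arr),
                )
            )
    return DiploidTruth(hap1=_decode(hap1), hap2=_decode(hap2), truth=truth)


def simulate_reads(
    truth: DiploidTruth,
    coverage: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Uniform substitution-error reads from both haplotypes.

    Coverage is total sequenced bases over the haploid genome length;
    the realised read count is exactly ``round(coverage * L /
    read_len)``.  Reads are drawn from a random haplotype and strand;
    errors are i.i.d. substitutions to a different base.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    L = truth.genome_len
    n_reads = int(round(coverage * L / read_len))
    if n_reads == 0:
        return []
    haps = [
        np.frombuffer(truth.hap1.encode(), dtype=np.uint8),
        np.frombuffer(truth.hap2.encode(), dtype=np.uint8),
    ]
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    hap_codes = [lut[h] for h in haps]

    which = rng.integers(0, 2, size=n_reads)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads: list[str] = []
    for w, s, st in zip(which, starts, strands):
        seg = hap_codes[w][s : s + read_len].copy()
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < error_rate)
            if errs.size:
                seg[errs] = (
                    seg[errs] + rng.integers(1, 4, size=errs.size).astype(np.uint8)
                ) % 4
        if st:
            seg = (seg[::-1] ^ 3).astype(np.uint8)
        reads.append(_decode(seg))
    return reads


def write_fastq(reads: Iterable[str], path: str | os.PathLike, quality: str = "I") -> None:
    """Write sequences as FASTQ with a fixed quality character."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")
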