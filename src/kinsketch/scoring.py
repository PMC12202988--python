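"""Genotyping and the two relationship scores.

Relatedness score: sites are genotyped heterozygous/homozygous by
comparing the ref fraction r/(r+a) against a data-driven cutoff (the
valley of the ref-fraction histogram), and the score is
Het/(Het+Hom).  Because sketch sites are heterozygous in the donor, an
identical sample scores ~1 and a first-degree relative ~0.5.

Likelihood score: a mean per-site -2 log likelihood ratio comparing the
query against an idealised heterozygote pseudo-sample with counts
(1, 1).  Per effective site (r + a >= 2) the binomial kernel is
evaluated at the per-sample MLEs (p1 = r/(r+a), p2 = 1/2) and at the
pooled MLE p* = (r+1)/(r+a+2); binomial coefficients cancel in the
ratio.  The statistic is always >= 0, tends to 0 with coverage for an
identical pair, and grows for unrelated or related-but-distinct pairs;
it is compared against the 0.63 decision bound.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .counting import SiteCounts
from .params import DEFAULT_PARAMS, Params

__all__ = [
    "GenotypeSummary",
    "LikelihoodResult",
    "ScoreReport",
    "genotype_cutoff",
    "call_genotypes",
    "relatedness_score",
    "likelihood_score",
    "classify",
    "score_sample",
]

HET, HOM, MISSING = "het", "hom", "missing"


@dataclasses.dataclass
class GenotypeSummary:
    """Per-site genotype labels plus Het/Hom totals."""

    ratio: np.ndarray  # ref/(ref+alt); NaN where uncovered
    labels: np.ndarray  # '<U7' het | hom | missing
    n_het: int
    n_hom: int
    cutoff: float


@dataclasses.dataclass
class LikelihoodResult:
    lambda_bar: float  # NaN when no effective sites
    n_effective: int
    lambdas: np.ndarray | None = None


@dataclasses.dataclass
class ScoreReport:
    sample: str
    sketch_individual: str
    relatedness_score: float
    likelihood_score: float
    n_sites: int
    n_effective: int
    verdict: str  # same | different | unreliable
    warnings: list[str]


def genotype_cutoff(ratios, params: Params = DEFAULT_PARAMS) -> float:
    """Valley of the ref-fraction histogram, searched in a fixed window.

    Builds a ``cutoff_bins``-bin histogram of the ratios on [0, 1] and
    returns the centre of the least-occupied bin with centre inside
    [cutoff_search_lo, cutoff_search_hi]; ties break toward the bin
    centre closest to ``cutoff_default`` (then toward the smaller
    centre).  With fewer than ``cutoff_min_sites`` covered sites the
    default cutoff is returned with a warning.
    """
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < params.cutoff_min_sites:
        warnings.warn(
            f"only {ratios.size} covered sites; using default genotype "
            f"cutoff {params.cutoff_default}",
            stacklevel=2,
        )
        return params.cutoff_default
    counts, edges = np.histogram(ratios, bins=params.cutoff_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_window = (centers >= params.cutoff_search_lo) & (
        centers <= params.cutoff_search_hi
    )
    idx = np.flatnonzero(in_window)
    cand = sorted(
        idx,
        key=lambda i: (counts[i], abs(centers[i] - params.cutoff_default), centers[i]),
    )
    return float(centers[cand[0]])


def call_genotypes(counts: SiteCounts, cutoff: float) -> GenotypeSummary:
    """Label covered sites het/hom by symmetric cutoff on the ref
    fraction: hom iff ratio >= cutoff or ratio <= 1 - cutoff (boundary
    values are hom); uncovered sites are missing."""
    if not 0.5 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0.5, 1)")
    r = counts.ref.astype(float)
    a = counts.alt.astype(float)
    tot = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot >= 1, r / tot, np.nan)
    labels = np.full(ratio.size, MISSING, dtype="<U7")
    covered = tot >= 1
    hom = covered & ((ratio >= cutoff) | (ratio <= 1.0 - cutoff))
    het = covered & ~hom
    labels[hom] = HOM
    labels[het] = HET
    return GenotypeSummary(
        ratio=ratio,
        labels=labels,
        n_het=int(het.sum()),
        n_hom=int(hom.sum()),
        cutoff=cutoff,
    )


def relatedness_score(summary: GenotypeSummary) -> float:
    """Het / (Het + Hom) over the query's labelled sites."""
    total = summary.n_het + summary.n_hom
    if total == 0:
        raise ValueError("no callable sites")
    return summary.n_het / total


def _lambda_sites(r: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Vectorised per-site -2 log LR against the (1, 1) pseudo-sample."""
    r = r.astype(float)
    a = a.astype(float)
    n = r + a
    p1 = r / n
    pstar = (r + 1.0) / (n + 2.0)

    def xlogy(x, y):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = x * np.log(y)
        return np.where(x == 0.0, 0.0, out)

    log_l1 = xlogy(r, p1) + xlogy(a, 1.0 - p1)
    log_l2 = 2.0 * np.log(0.5)
    log_lstar = (
        xlogy(r, pstar)
        + xlogy(a, 1.0 - pstar)
        + np.log(pstar)
        + np.log(1.0 - pstar)
    )
    lam = -2.0 * (log_lstar - log_l1 - log_l2)
    return np.maximum(lam, 0.0)  # clip float jitter at the λ=0 boundary


def likelihood_score(
    counts: SiteCounts, params: Params = DEFAULT_PARAMS, keep_lambdas: bool = False
) -> LikelihoodResult:
    """Mean -2 log-likelihood-ratio score over effective sites.

    Effective sites have ref + alt >= 2, using the per-allele maximum
    slot counts (the low-coverage-sensitive reduction).  With zero
    effective sites the score is NaN and the verdict downstream is
    "unreliable".
    """
    r = counts.ref_max.astype(np.int64)
    a = counts.alt_max.astype(np.int64)
    eff = (r + a) >= 2
    n_eff = int(eff.sum())
    if n_eff == 0:
        return LikelihoodResult(lambda_bar=float("nan"), n_effective=0)
    lam = _lambda_sites(r[eff], a[eff])
    return LikelihoodResult(
        lambda_bar=float(lam.mean()),
        n_effective=n_eff,
        lambdas=lam if keep_lambdas else None,
    )


def classify(
    relatedness: float,
    likelihood: LikelihoodResult,
    params: Params = DEFAULT_PARAMS,
    sample: str = "query",
    sketch_individual: str = "sketch",
    n_sites: int = 0,
    extra_warnings: list[str] | None = None,
) -> ScoreReport:
    """Verdict from the likelihood score and effective-site count.

    Fewer than ``min_effective_sites`` effective sites always yields
    "unreliable".  Otherwise the verdict is "same" when the score falls
    on the identical side of ``identity_threshold`` (the low side by
    default: the score of an identical pair tends to 0 with coverage),
    "different" otherwise.
    """
    warns = list(extra_warnings or [])
    n_eff = likelihood.n_effective
    if n_eff < params.min_effective_sites:
        verdict = "unreliable"
        warns.append(
            f"only {n_eff} effective sites (< {params.min_effective_sites}); "
            "verdict is unreliable"
        )
    else:
        low = likelihood.lambda_bar <= params.identity_threshold
        same = low if params.identity_low_side else not low
        verdict = "same" if same else "different"
    return ScoreReport(
        sample=sample,
        sketch_individual=sketch_individual,
        relatedness_score=relatedness,
        likelihood_score=likelihood.lambda_bar,
        n_sites=n_sites,
        n_effective=n_eff,
        verdict=verdict,
        warnings=warns,
    )


def score_sample(
    counts: SiteCounts,
    params: Params = DEFAULT_PARAMS,
    sketch_individual: str = "sketch",
) -> ScoreReport:
    """Convenience: cutoff -> genotypes -> both scores -> verdict."""
    extra: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cutoff = genotype_cutoff(
            np.where(
                counts.ref + counts.alt >= 1,
                counts.ref / np.maximum(counts.ref + counts.alt, 1),
                np.nan,
            ),
            params,
        )
    extra.extend(str(w.message) for w in caught)
    summary = call_genotypes(counts, cutoff)
    total = summary.n_het + summary.n_hom
    rel = relatedness_score(summary) if total else float("nan")
    if total == 0:
        extra.append("no callable sites for the relatedness score")
    lik = likelihood_score(counts, params)
    return classify(
        rel,
        lik,
        params,
        sample=counts.sample,
        sketch_individual=sketch_individual,
        n_sites=counts.n_sites,
        extra_warnings=extra,
    )
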