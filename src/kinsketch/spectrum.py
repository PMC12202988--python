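"""k-mer spectrum peak detection, heterozygous region choice and a rough
two-component negative-binomial genome profile.

A diploid k-mer spectrum typically shows an error spike at frequency 1,
a heterozygous peak near the per-haplotype k-mer coverage c, and a
homozygous peak near 2c.  Stage 1 only needs the heterozygous frequency
window; the NB mixture fit is a sanity report for the user, not part of
the calling path.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize, stats

from .kmers import KmerHistogram
from .params import DEFAULT_PARAMS, Params

__all__ = [
    "Peak",
    "HetRegion",
    "GenomeProfile",
    "NoPeakError",
    "detect_peaks",
    "select_het_peak",
    "het_region",
    "fit_two_nb",
]


@dataclasses.dataclass(frozen=True)
class Peak:
    freq: int
    height: int


@dataclasses.dataclass(frozen=True)
class HetRegion:
    """Inclusive frequency window presumed to hold heterozygous k-mers."""

    lo: int
    hi: int
    het_peak: int

    def __post_init__(self) -> None:
        if not (2 <= self.lo <= self.hi):
            raise ValueError(f"invalid region [{self.lo}, {self.hi}]")

    def __contains__(self, freq: int) -> bool:
        return self.lo <= freq <= self.hi


class NoPeakError(RuntimeError):
    pass


def _round_half_up(x: float) -> int:
    # half away from zero for the (positive) quantities used here
    return int(math.floor(x + 0.5))


def detect_peaks(hist: KmerHistogram, params: Params = DEFAULT_PARAMS) -> list[Peak]:
    """Scan the spectrum left to right for 3-point local maxima.

    A peak is a frequency f with hist[f-1] < hist[f] > hist[f+1].  The
    scan covers at most the first ``hist_max_entries`` frequencies and
    terminates early once ``max_peaks`` peaks were found or once the
    cumulative k-mer mass reaches ``hist_mass_stop`` of the total; both
    rules suppress small noise peaks far in the tail.  Frequency 1 has
    no left neighbour and can never be a peak, but its (error-
    dominated) mass counts toward the stop rule.
    """
    if hist.freq.size == 0:
        return []
    fmax = min(params.hist_max_entries, hist.max_freq)
    dense = hist.dense(fmax + 1)  # hist[fmax+1] used as right neighbour
    total_mass = hist.total_mass
    stop_mass = params.hist_mass_stop * total_mass

    peaks: list[Peak] = []
    cum = 0
    for f in range(1, fmax + 1):
        if f >= 2 and dense[f - 1] < dense[f] > dense[f + 1]:
            peaks.append(Peak(freq=f, height=int(dense[f])))
            if len(peaks) >= params.max_peaks:
                break
        cum += f * dense[f]
        if cum >= stop_mass:
            break
    return peaks


def select_het_peak(
    peaks: list[Peak], high_het: bool, params: Params = DEFAULT_PARAMS
) -> int:
    """Choose the heterozygous peak frequency.

    Two peaks: the first (lower-frequency) one is heterozygous.  One
    peak: with a high-heterozygosity species (rate > ~1.2%) the lone
    peak is heterozygous; otherwise it is homozygous and the
    heterozygous coverage sits at half its frequency (diploid
    expectation), clamped to >= 2.
    """
    if not peaks:
        raise NoPeakError("no peak detected; increase coverage or check data")
    if len(peaks) >= 2:
        return peaks[0].freq
    if high_het:
        return peaks[0].freq
    return max(2, _round_half_up(peaks[0].freq / 2))


def het_region(het_peak: int, params: Params = DEFAULT_PARAMS) -> HetRegion:
    """0.5x-1.5x window around the heterozygous peak, left floor 2."""
    if het_peak < 1:
        raise ValueError("het_peak must be >= 1")
    lo = max(params.min_region_lo, _round_half_up(params.region_lo_mult * het_peak))
    hi = _round_half_up(params.region_hi_mult * het_peak)
    return HetRegion(lo=lo, hi=max(lo, hi), het_peak=het_peak)


@dataclasses.dataclass
class GenomeProfile:
    """Rough genome characteristics from a 2-NB spectrum fit."""

    het_coverage: float
    hom_coverage: float
    het_dispersion: float
    hom_dispersion: float
    het_weight: float
    heterozygosity_estimate: float
    genome_size_estimate: float
    fit_ok: bool
    message: str = ""

    def report(self) -> str:
        if not self.fit_ok:
            return f"genome profile: fit failed ({self.message})"
        return (
            "genome profile (rough 2-NB fit):\n"
            f"  het k-mer coverage : {self.het_coverage:.2f}\n"
            f"  hom k-mer coverage : {self.hom_coverage:.2f}\n"
            f"  heterozygosity     : {self.heterozygosity_estimate:.4f}\n"
            f"  genome size        : {self.genome_size_estimate:,.0f} bp"
        )


def _nb_pmf(f: np.ndarray, mean: float, size: float) -> np.ndarray:
    # negative binomial parameterised by mean and size (dispersion)
    p = size / (size + mean)
    return stats.nbinom.pmf(f, size, p)


def fit_two_nb(
    hist: KmerHistogram,
    het_peak: int,
    params: Params = DEFAULT_PARAMS,
    k: int | None = None,
) -> GenomeProfile:
    """Fit a_1 NB(mean~c) + a_2 NB(mean~2c) to the spectrum above the
    error region and derive rough genome characteristics.

    The fit never raises: optimizer failures or degenerate histograms
    yield ``fit_ok=False``.  Genome size is the k-mer mass above the
    error region divided by the homozygous coverage; heterozygosity is
    the fitted number of heterozygous k-mers divided by 2k per site and
    the genome size (each isolated het site contributes ~2k distinct
    heterozygous k-mers).
    """
    kk = params.k if k is None else k
    fail = GenomeProfile(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, False)
    if hist.freq.size == 0:
        fail.message = "empty histogram"
        return fail
    lo = het_region(het_peak, params).lo
    fit_hi = min(hist.max_freq, max(6 * het_peak, lo + 10))
    sel = (hist.freq >= lo) & (hist.freq <= fit_hi)
    f = hist.freq[sel].astype(float)
    y = hist.n_distinct[sel].astype(float)
    if f.size < 10:
        fail.message = "fewer than 10 informative frequencies above the error region"
        return fail

    mass_above = float((hist.freq[hist.freq >= lo] * hist.n_distinct[hist.freq >= lo]).sum())
    a_tot = float(y.sum())

    def model(ff, a1, m1, s1, a2, m2, s2):
        return a1 * _nb_pmf(ff, m1, s1) + a2 * _nb_pmf(ff, m2, s2)

    p0 = [0.2 * a_tot, float(het_peak), 10.0, 0.8 * a_tot, 2.0 * het_peak, 10.0]
    bounds = (
        [0.0, max(1.0, 0.3 * het_peak), 0.3, 0.0, 1.2 * het_peak, 0.3],
        [5 * a_tot, 1.5 * het_peak, 1e4, 5 * a_tot, 4.0 * het_peak, 1e4],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model, f, y, p0=p0, bounds=bounds, maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        fail.message = f"optimizer failed: {exc}"
        return fail

    a1, m1, s1, a2, m2, s2 = (float(v) for v in popt)
    if m2 <= m1 or m2 <= 0:
        fail.message = "degenerate component means"
        return fail
    genome_size = mass_above / m2 if m2 > 0 else 0.0
    het_sites = a1 / (2 * kk)
    het_rate = min(1.0, het_sites / genome_size) if genome_size > 0 else 0.0
    return GenomeProfile(
        het_coverage=m1,
        hom_coverage=m2,
        het_dispersion=s1,
        hom_dispersion=s2,
        het_weight=a1 / (a1 + a2) if a1 + a2 > 0 else 0.0,
        heterozygosity_estimate=het_rate,
        genome_size_estimate=genome_size,
        fit_ok=True,
    )
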