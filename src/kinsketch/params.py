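"""Global constants for the two-stage identity-check pipeline.

All tunables live in a single frozen dataclass so that stage 1 (sketch
construction) and stage 2 (counting/scoring) agree on k and on every
threshold.  The defaults encode the published operating point of the
method: 21-mers, a heterozygous window of 0.5x-1.5x around the
heterozygous spectrum peak with a floor of 2, a full-support filter of
length k, a minimum of 50 effective sites for a reliable verdict, and an
identity decision bound of 0.63 on the mean log-likelihood-ratio score.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class Params:
    """Pipeline constants.

    Parameters
    ----------
    k : int
        Odd k-mer size (3..31; 21 by default).  21 balances SNP-calling
        specificity against redundancy for high-error query data.
    region_lo_mult, region_hi_mult : float
        The heterozygous frequency region spans
        ``[region_lo_mult * peak, region_hi_mult * peak]``.
    min_region_lo : int
        Floor of the region's left boundary; excludes frequency-1/2
        error k-mers.
    hist_max_entries : int
        Peak detection scans at most this many histogram entries.
    hist_mass_stop : float
        Peak detection stops early once this fraction of the total k-mer
        mass has been scanned.
    max_peaks : int
        Peak detection stops after this many peaks (2: het + hom).
    high_het_cutoff : float
        Heterozygosity fraction above which a lone spectrum peak is
        taken to be the heterozygous peak rather than the homozygous
        one.
    support_required : int or None
        Only SNP pairs whose support length equals this value survive
        the stage-1 filter.  ``None`` (default) means full support k,
        i.e. every overlapping window pair is present in the
        heterozygous set.
    min_effective_sites : int
        Below this number of effective sites (ref+alt >= 2) the verdict
        is "unreliable".
    min_sketch_sites : int
        Stage 1 warns when fewer sites than this make it into the
        sketch (~20k sites keep >= 50 effective sites even for 0.5x
        high-error queries).
    identity_threshold : float
        Decision bound on the mean log-likelihood-ratio score.
    identity_low_side : bool
        True: scores <= identity_threshold mean "same individual" (the
        default under the binomial kernel used here, where the score of
        an identical pair tends to 0 with coverage).
    cutoff_bins : int
        Number of histogram bins used for the ref-fraction valley
        search.
    cutoff_search_lo, cutoff_search_hi : float
        Window of ref-fraction values searched for the genotype cutoff
        valley.
    cutoff_default : float
        Fallback genotype cutoff when too few sites are available.
    cutoff_min_sites : int
        Minimum number of covered sites required to estimate the cutoff
        from data.
    matching_exact_max_nodes : int
        Connected components larger than this fall back from exact
        blossom matching to deterministic greedy matching.
    early_stop_check_reads : int
        Stage-2 early termination checks mean sketch coverage every
        this many reads.
    sim_sites, sim_p_het, sim_reps : int, float, int
        Defaults of the count-level simulation: 200k heterozygous
        sites, binomial allele split with P = 0.5, 1000 replicates.
    """

    k: int = 21
    region_lo_mult: float = 0.5
    region_hi_mult: float = 1.5
    min_region_lo: int = 2
    hist_max_entries: int = 1000
    hist_mass_stop: float = 0.95
    max_peaks: int = 2
    high_het_cutoff: float = 0.012
    support_required: int | None = None
    min_effective_sites: int = 50
    min_sketch_sites: int = 20000
    identity_threshold: float = 0.63
    identity_low_side: bool = True
    cutoff_bins: int = 50
    cutoff_search_lo: float = 0.60
    cutoff_search_hi: float = 0.90
    cutoff_default: float = 0.75
    cutoff_min_sites: int = 200
    matching_exact_max_nodes: int = 400
    early_stop_check_reads: int = 100_000
    sim_sites: int = 200_000
    sim_p_het: float = 0.5
    sim_reps: int = 1000

    def __post_init__(self) -> None:
        if not (3 <= self.k <= 31) or self.k % 2 == 0:
            raise ValueError(f"k must be odd and in [3, 31], got {self.k}")
        if self.region_lo_mult <= 0 or self.region_hi_mult <= 0:
            raise ValueError("region multipliers must be positive")
        if self.region_hi_mult < self.region_lo_mult:
            raise ValueError("region_hi_mult < region_lo_mult")
        if self.identity_threshold <= 0:
            raise ValueError("identity_threshold must be positive")
        if self.support_required is not None and not (
            1 <= self.support_required <= self.k
        ):
            raise ValueError("support_required must be in [1, k]")
        if not (0 < self.hist_mass_stop <= 1):
            raise ValueError("hist_mass_stop must be in (0, 1]")

    @property
    def full_support(self) -> int:
        """Resolved support-length filter (defaults to k)."""
        return self.k if self.support_required is None else self.support_required


DEFAULT_PARAMS = Params()
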