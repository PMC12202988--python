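# Methods

kinsketch verifies whether whole-genome sequencing runs come from the
same diploid individual without any reference genome. It works in two
stages: stage 1 calls isolated heterozygous SNPs from one low-error run
by k-mer analysis and stores them as a *variant sketch*; stage 2 counts
sketch k-mers in any other run — any sequencing technology — and turns
the counts into two relationship scores.

## Stage 1: isolated heterozygous SNP calling

**k-mer counting.** Reads are decomposed into 21-mers (two bits per
base, A=0 < C=1 < G=2 < T=3, so integer order equals lexicographic
order). Each k-mer is stored canonically as the smaller of itself and
its reverse complement, making counts strand independent. Windows
containing non-ACGT characters are skipped whole (not split), the rule
most k-mer counters use. The abundance histogram records the number of
distinct k-mers at each occurrence frequency.

**Heterozygous region.** A diploid spectrum shows an error spike at
frequency 1, a heterozygous peak near the per-haplotype k-mer coverage
c, and a homozygous peak near 2c. The peak scan walks the first 1,000
histogram entries looking for 3-point local maxima
(`hist[f-1] < hist[f] > hist[f+1]`; plateaus are not peaks, and
frequency 1 has no left neighbour so it can never be one) and stops
early after two peaks or once 95% of the total k-mer mass has been
read — both rules suppress small noise peaks in the long tail. With two
peaks the first is heterozygous. With one peak the interpretation
depends on the species: above ~1.2% heterozygosity the het peak
dominates and the lone peak is taken as heterozygous (the `high_het`
flag); otherwise it is homozygous and the het coverage is half its
frequency (rounded half away from zero, clamped to >= 2). The
heterozygous region is then 0.5x-1.5x of the het peak, with a left
floor of 2 to exclude error k-mers. A two-component negative-binomial
fit of the spectrum above the error region (scipy `curve_fit`,
mean/size parameterisation, components initialised at c and 2c)
produces a rough genome profile — het/hom coverage, genome size
(k-mer mass over hom coverage) and a heterozygosity estimate (fitted
het k-mers over 2k per site over genome size). The fit is advisory
only: failures set `fit_ok=False` and never block calling.

**Pairing and support.** K-mers whose counts fall inside the region
form the vertex set. Two vertices are joined when some orientation of
one differs from some orientation of the other at exactly the middle
base — an isolated SNP produces exactly such a pair, one k-mer per
allele. Pairing is orientation-aware because the middle-base property
is not preserved by canonicalisation; each pair is recorded once with
the presentation whose first oriented k-mer is smallest. Each pair's
*support length* is computed by walking the shared flanks outwards: a
step in a direction succeeds iff exactly one base keeps both shifted
allele windows inside the heterozygous set. If more than one base
succeeds the walk stops in that direction — a conservative rule that
avoids chimeric contexts assembled from unrelated reads. Support is
1 + left + right steps, at most k.

**Selection.** A maximum-weight matching over the pair graph (weights =
support lengths) picks a consistent SNP set: each k-mer backs at most
one call. Connected components are solved independently with the exact
blossom algorithm (networkx); ties between equal-weight matchings are
broken toward lexicographically smaller code pairs by a rank penalty
too small to change the optimal weight, which makes the output
deterministic. Components beyond `matching_exact_max_nodes` (default
400; never reached in our simulations, where components are almost
always single edges) fall back to deterministic greedy matching. Only
full-support calls (support == 21) are kept; this filter is what holds
precision above 90% at low coverage, at the cost of recall. The two
41 bp allele contexts are reconstructed from the extension walk; "ref"
vs "alt" is an arbitrary but deterministic label (lexicographically
smaller context first) since no reference exists.

## Sketch construction and counting

Each call's ref and alt contexts are sliced into their 21 windows and
canonicalised. Any canonical k-mer occurring more than once anywhere in
the sketch — within a site, across sites, across alleles, or across
merged individuals — is removed from *all* positions: a shared k-mer
cannot attribute query counts to a single site/allele, so keeping any
copy would break site independence (the stricter of the two possible
dedup readings; the removal rule is re-applied on merge). Sites left
without at least one k-mer per allele are dropped. The sketch FASTA
stores one record per retained k-mer (`>site{ID}|{allele}|{index}`),
making the file self-validating on read.

Stage 2 hashes the sketch k-mers with a reversible 64-bit mixer (the
splitmix64 finalizer; bijectivity means the table key can always be
mapped back to its k-mer, and the exact inverse is implemented) and
streams query reads through the table, incrementing a slot whenever a
window matches. An optional expected-coverage bound stops reading once
the mean count over all sketch slots reaches it (checked every 100k
reads), making counts read-order dependent only through the stopping
point.

## Scores

Per site, the slot vectors are reduced to scalars two ways:

* **mode** (ties toward the smaller value) — robust against single
  inflated slots (e.g. counts 8, 9, 8, 7 give 8, where the maximum
  would give 9); used for genotyping and the relatedness score;
* **maximum** — sensitive when coverage is far below 1x and most slots
  are 0; used for the likelihood score's effective-site counts.

Applying the mode to the likelihood path too would zero out nearly all
sites below ~2x coverage and defeat the 50-effective-site machinery,
which is why the two scores use different reductions (the mode
stabilises genotypes against error-inflated slots; the maximum is the
reduction reference-based identity checkers conventionally use).

**Relatedness score.** Sites with ref+alt >= 1 are genotyped by the
ref fraction r/(r+a): hom iff the fraction is >= v or <= 1-v, het
otherwise, where the cutoff v is the valley of the 50-bin ref-fraction
histogram searched within [0.60, 0.90] (ties toward 0.75; with fewer
than 200 covered sites the default 0.75 is used with a warning). The
score is Het/(Het+Hom). Because sketch sites are heterozygous in the
donor by construction, an identical sample scores ~1 and a first-degree
relative — sharing half the heterozygous sites — ~0.5. The score is
only meaningful at substantial coverage (recommended >= 20x).

**Likelihood score.** For sample-swap detection at low coverage, each
*effective* site (ref+alt >= 2) contributes a -2 log likelihood ratio
comparing "query and an idealised heterozygote are one sample" against
"they are independent". The idealised heterozygote is a pseudo-sample
with fixed counts (1, 1). With query counts (r, a), the binomial kernel
is evaluated at the per-sample MLEs p1 = r/(r+a) and p2 = 1/2 and at
the pooled MLE p* = (r+1)/(r+a+2); binomial coefficients cancel in the
ratio and natural logs are used:

    lambda = -2 [ (r ln p* + a ln q* + ln p* + ln q*)
                  - (r ln p1 + a ln q1) - 2 ln 1/2 ],   q = 1 - p

lambda is >= 0 by construction (a constrained maximum never exceeds the
unconstrained product) and symmetric in (r, a). The score is the mean
over effective sites. For an identical pair it tends to 0 with
coverage (~0.068 at 30x with 200k sites); for a first-degree pair the
homozygous half of the sites contributes large terms (~3.1 at 30x).
The verdict compares the mean against the 0.63 decision bound — scores
at or below it mean "same individual"; the direction and threshold are
configurable (`--flip-direction`, `--threshold`) because the bound was
calibrated externally. Fewer than 50 effective sites always yields
"unreliable", and stage 1 warns below ~20k sketch sites because that is
what keeps 50 effective sites reachable for 0.5x high-error queries.

## Synthetic data

**Count-level simulation** (score calibration): a sketch of 200,000
heterozygous sites; per site depth d ~ Poisson(coverage); identical
pair: ref ~ Binomial(d, 0.5), alt = d - ref; first-degree pair: an
independent random half of sites is binomial, the other half places the
full depth on one uniformly chosen allele (the relative is homozygous
there, with no linkage between sites). The replicated study (default
1,000 reps over coverages 0.1x-30x) records the mean, 1st and 99th
percentiles of the likelihood score per cell.

**Sequence-level simulation** (end-to-end tests): a uniform random
genome (or a supplied backbone shared between individuals of one
species); heterozygous substitutions planted by a renewal process with
gaps (2k-1) + Geometric, mean 1/het_rate, so SNPs are guaranteed
isolated with variant-free 41 bp flanks; reads of fixed length drawn
uniformly from both haplotypes and strands with i.i.d. substitution
errors. Defaults for the scaled-down calling experiment follow the
stated world: 2 Mb genome, 1% heterozygosity, 150 bp reads, 0.2%
error. What this generator does *not* emulate: repeats and homologous
sequence families (the main source of false SNP k-mer pairs in real
genomes), indels, coverage biases and homopolymer-dependent error
profiles. A green end-to-end test therefore establishes the internal
consistency of the pipeline, not its robustness to repeat-rich genomes.

## Known limitations and numerical choices

* **Low-coverage spectra can be peakless.** At 1% heterozygosity and
  4x coverage with 150 bp reads, the het (mean ~1.7) and hom (~3.5)
  k-mer components merge below the error spike into a strictly
  decreasing histogram; no 3-point local maximum exists and stage 1
  refuses with "no peak detected". This is a property of the mixture,
  not of the detector — peak recovery is only claimed at >= 6x. Human
  data at ~0.1% heterozygosity does not show the degeneracy at 4x
  because the hom peak is not swamped.
* **The identity bound needs moderate coverage under this kernel.** At
  depth-2 effective sites an identical pair still produces (2,0)/(0,2)
  splits a quarter of the time (lambda = 1.726), so the identical-pair
  mean score stays above 0.63 below ~3.5x query coverage; the verdict
  is reliable from ~4x upward in clean data. A richer likelihood with
  explicit error-rate terms would shift this; such terms are
  deliberately out of scope here.
* Rounding of region bounds is half-away-from-zero; the genotype-cutoff
  boundary value is homozygous; modal ties break toward the smaller
  count; all tie-breaks are documented and deterministic.
* Site ids are assigned by sorted ref context, so sketches are
  reproducible regardless of read order; all randomness in the
  simulators flows from a single seed.
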