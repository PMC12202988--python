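# kinsketch

Reference-free detection of sample swaps and first-degree relationships
in whole-genome sequencing cohorts.

Sample mislabeling is a common failure mode in sequencing projects, and
the standard guards (genotyping a panel of known variant sites) need a
reference genome and a variant catalogue. kinsketch needs neither. It
is aimed at QC of WGS runs for any diploid species:

* **Stage 1** takes one low-error run (Illumina/HiFi-like) from the
  target individual, calls isolated heterozygous SNPs directly from the
  k-mer spectrum, and stores them as a *variant sketch* — per-site
  ref/alt 21-mer sets, deduplicated so every k-mer is unique.
* **Stage 2** streams any other run (including high-error long reads)
  against the sketch, counts k-mer matches per site, and scores the
  relationship.

Two scores are reported per (sample, sketch) pair. Sites are genotyped
from the modal ref/alt counts and the **relatedness score** is

    Het_i / (Het_i + Hom_i)

over the query's genotypes at sketch sites — ~1 for the same
individual, ~0.5 for a parent/child or sibling (sketch sites are
heterozygous in the donor by construction). The **likelihood score**
handles low coverage: per effective site (ref+alt >= 2) a -2 log
likelihood ratio compares the query against an idealised heterozygote
pseudo-sample with counts (1, 1), using a binomial kernel with pooled
vs per-sample MLEs, and the mean over effective sites is compared
against the 0.63 decision bound (identical pairs fall below it, and
toward 0 as coverage grows). Fewer than 50 effective sites always
yields an "unreliable" verdict. See `docs/methods.md` for the model,
assumptions and limitations.

## Worked example

Simulate two individuals of one species (shared backbone, individual
het sites), sketch individual A from 10x reads, and check both at 4x:

```python
import numpy as np
import kinsketch as ks

rng = np.random.default_rng(42)
backbone = rng.integers(0, 4, 2_000_000, dtype=np.uint8)
A = ks.simulate_diploid(2_000_000, 0.01, seed=11, genome=backbone)
B = ks.simulate_diploid(2_000_000, 0.01, seed=22, genome=backbone)

reads_a10 = ks.simulate_reads(A, 10, 150, 0.002, seed=1)
calls = ks.call_snps(reads_a10)                 # stage 1
sketch = ks.build_sketch(calls, individual="A")
index = ks.index_sketch(sketch)

for name, who in (("A", A), ("B", B)):
    reads = ks.simulate_reads(who, 4, 150, 0.002, seed=99)
    counts = ks.count_sample(reads, index, sample=name)  # stage 2
    r = ks.score_sample(counts)
    print(name, f"relatedness={r.relatedness_score:.3f}",
          f"likelihood={r.likelihood_score:.3f}",
          f"N={r.n_effective}", r.verdict)
```

Output:

```
A relatedness=0.624 likelihood=0.512 N=5127 same
B relatedness=0.002 likelihood=2.561 N=5072 different
```

A's 4x run scores 0.512 — below the 0.63 bound, so it is the same
individual (the relatedness score is noisy at 4x; it needs ~20x to
approach 1). B shares the species backbone but not A's heterozygous
sites, so almost every site looks homozygous, the likelihood score is
far above the bound, and the verdict is "different".

The same pipeline from the shell:

```bash
kinsketch sketch --reads A_10x.fq.gz --k 21 --high-het no --out-prefix A
kinsketch check  --sketch A.sketch.fa --samples B_4x.fq.gz --out report.csv
kinsketch simulate --sites 200000 --reps 1000 --seed 0 --out study.csv
```

`check` writes one CSV row per sample with both scores, the effective
site count, the verdict and any warnings; `simulate` reproduces the
count-level calibration study (mean/1st/99th percentile of the
likelihood score per coverage and relationship).

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline numbers from
scratch by running the code above at full scale: the relatedness
identities of identical and first-degree pairs on the count-level
simulation (200k sites at 30x), the stage-1 SNP-calling precision on a
simulated 2 Mb diploid genome at 4-10x coverage, and the 99th/1st
percentiles of the likelihood score for identical/first-degree pairs
at 30x across 100 replicates:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes about a minute on one CPU and writes one JSON entry per
quantity.
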