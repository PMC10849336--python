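# lpimpute

Low-pass whole-genome sequencing (lpWGS) plus imputation, evaluated end to
end. The package is aimed at people who design or QC low-pass genotyping
pipelines and want to reason quantitatively about how sequencing-library
properties — above all the duplicate-read rate — propagate through coverage
evenness into imputation accuracy, without needing a real sequencing run to
do it.

## What it computes

**Effective coverage.** For a sample imputed against a haplotype reference
panel, the informative quantity is not the nominal coverage (sequenced bases
÷ genome size) but

&nbsp;&nbsp;&nbsp;&nbsp;λ_eff = −ln(1 − f_covered),

where f_covered is the fraction of panel sites covered by ≥1 deduplicated
read with base quality ≥ 13. Under uniform Poisson sampling λ_eff equals the
true mean depth; duplicates and uneven coverage push it below the nominal
coverage, so the ratio λ_eff / λ_nominal measures sequencing evenness.

**Genotype imputation.** Filtered pileup counts at panel sites become
binomial genotype likelihoods, which feed an exact diploid Li–Stephens
haplotype-copying HMM: the hidden state is an ordered pair of panel
haplotypes, each copying process switches to a uniformly chosen haplotype
with probability `recomb_scale` per interval, and the copied allele pair
emits the read data through a `copy_error` mismatch parameter. Imputation is
leave-one-out: the sample's own two haplotypes are removed from the panel,
so its panel genotypes serve as held-out truth. Sites where no genotype
posterior exceeds 0.9 are flagged low-confidence and dropped.

**Non-reference concordance (NRC).** Accuracy against truth is genotype
concordance over the site intersection after discarding sites where *both*
call sets are homozygous reference — the sites that dominate plain
concordance while carrying no information. NRC is reported overall and
stratified by panel allele frequency (folded to minor-allele frequency).

**Group comparison.** Per-sample metrics are summarised as mean (SD) and
compared between groups with an unpaired two-sample Welch's t-test
(Welch–Satterthwaite degrees of freedom, two-sided p).

A synthetic-data module generates haplotype panels with a configurable site
frequency spectrum and linkage disequilibrium, recombinant-mosaic truth
individuals, and per-site read pileups with tunable coverage,
overdispersion, duplicate rate, base error and base qualities — so the whole
pipeline runs and is tested with no external data.

## Worked example

```python
import numpy as np
import lpimpute as lp

panel = lp.generate_panel(n_haplotypes=40, n_sites=2000, seed=1)
ind = lp.simulate_individual(panel, seed=2)
cfg = lp.ReadSimConfig(nominal_coverage=0.8, dup_rate=0.0027)
pileups, tally = lp.simulate_pileup(ind, panel, cfg, rng=np.random.default_rng(3))

cov = lp.summarize_coverage(pileups, tally)
print(cov.summary().to_string(index=False))

lik = lp.likelihoods_from_pileups(pileups, cfg.base_error)
post = lp.impute_sample(lik, panel, ind.hap_indices)   # leave-one-out
filt = lp.filter_posteriors(post)
rep = lp.nrc(filt.calls, ind.genotypes)
print(f"NRC = {rep.nrc:.3f} over {rep.n_denom} non-reference sites "
      f"({filt.n_filtered} low-confidence sites removed)")
```

prints

```
 nominal_coverage  f_covered  lambda_eff  eff_to_nominal_ratio  dup_rate  n_sites       mode
            0.793      0.547    0.791863              0.998566  0.003153     2000 simulation
NRC = 0.638 over 431 non-reference sites (545 low-confidence sites removed)
```

The sample drew 0.793 raw reads per panel site, 54.7% of sites got at least
one passing read, and −ln(1−0.547) = 0.79 recovers the nominal coverage
almost exactly (ratio 0.999) because this simulation is Poisson-uniform with
a 0.3% duplicate rate. At 0.8× depth with a 40-haplotype panel, imputation
gets 63.8% of the informative (non-double-hom-ref) confident sites right;
accuracy climbs steeply with coverage and with panel size.

The same steps are available from the shell (`lpimpute simulate`,
`coverage`, `impute`, `concord`, `compare`, `run-experiment`), consuming and
producing standard formats: samtools-mpileup text or a TSV pileup dialect,
VCF for panels/truth/imputed calls (GT + GP, `LOWCONF` filter), TSV reports.

The full two-arm study — two groups of samples whose read simulations differ
only in duplicate rate (0.27% vs 5.5%, the low- and high-duplication
chemistry regimes) — runs with

```sh
lpimpute run-experiment --n-samples 20 --out-dir study --plots
```

and writes per-sample metrics, per-arm summaries, Welch comparisons of
duplication rate / evenness ratio / NRC, and NRC-by-allele-frequency tables.

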