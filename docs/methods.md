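# Methods

This note documents the models implemented in `lpimpute`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic data can show.

## Synthetic data

### Haplotype panel

`generate_panel` builds an H-haplotype × M-site biallelic-SNP panel.
Per-site derived-allele counts are drawn i.i.d. from P(count = i) ∝
i^(−`sfs_exponent`) on i ∈ [1, H−1], so every site is polymorphic by
construction and `sfs_exponent = 1` gives the neutral site-frequency
spectrum. Exponents above 1 tilt the spectrum toward singletons; below 1
toward intermediate frequencies.

Linkage disequilibrium comes from a carrier-set copying rule: with
probability `ld_strength` a site's carrier set is derived from the previous
site's set (randomly shrunk or grown to the drawn allele count), otherwise
it is a fresh uniform subset. This gives exact control of the marginal SFS,
monotone control of adjacent-site haplotype correlation, and O(M) cost. It
is *not* a coalescent model: LD decays geometrically with distance, there is
no shared genealogy across sites, and no population growth or bottleneck
signatures. A full coalescent simulator was deliberately not used — the
analysis only needs tunable SFS and LD knobs, and this construction makes
both directly steerable.

Sites are placed every 1000 bp on one chromosome with random distinct
ref/alt bases; `genetic_dist` defaults to 1 per interval, so the HMM's
`recomb_scale` reads directly as a per-interval switch probability.

### Truth individual

`simulate_individual` mirrors the copying model generatively: each of the
two haplotypes starts on a uniformly chosen distinct panel row, switches to
a uniformly chosen row with probability `recomb_rate` per interval
(default 0.001), and flips the copied allele with probability
`mutation_rate` per site (default 0.001). The two starting rows are
recorded and excluded from the panel at imputation time (leave-one-out);
rows visited after switches stay in the panel, which mimics a panel that
contains haplotypes related to, but not identical with, the sample.

### Reads

`simulate_pileup` draws per-site raw read counts as Poisson(λ) with
λ = `nominal_coverage` (default 0.8, the low-pass regime), or negative
binomial with variance λ + φλ² when `overdispersion` φ > 0. Each raw read is
independently a duplicate with probability `dup_rate`; duplicates replicate
the allele and quality of a previously drawn unique read at the site (a
duplicate landing where no unique read exists draws fresh values but stays
flagged) and are excluded from the filtered counts, so the unique-read depth
is an exact Binomial thinning of the raw depth — Poisson(λ(1−d)) in the
Poisson case. Duplicate flags are derived by thresholding a shared uniform
stream, so two configurations run with the same random state have *nested*
duplicate sets: paired comparisons across duplicate rates are coupled, which
is what makes the per-replicate ordering of evenness ratios nearly
deterministic.

Unique reads pick one of the two truth haplotypes with equal probability,
miscall the allele (ref↔alt) with probability `base_error` (default 0.002),
and carry a Phred quality drawn from `bq_distribution` (default all Q30;
mixtures with sub-13 mass exercise the coverage filter). Reads below the
base-quality threshold (default Phred 13) are excluded from pileup counts at
generation time, matching how real pileups are produced upstream.

Not emulated, by design: read length and overlapping-read geometry (the
analysis consumes per-site pileups only), indels and multiallelic sites,
alignment and mapping artifacts, reference bias, sex chromosomes, and
real-genome coverage unevenness beyond the single overdispersion knob.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated sampling assumptions, not robustness to everything real data can do.

## Effective coverage

`effective_coverage` computes λ_eff = −ln(1 − f_covered), with f_covered the
fraction of panel sites having ≥1 deduplicated, BQ-passing read. Under
Poisson sampling P(site uncovered) = e^(−λ), so λ_eff is the depth the
observed void fraction implies; duplicates re-sample covered positions and
lower it. f_covered = 1 raises a saturation error rather than returning
infinity — the low-pass regime never saturates, and a silent infinity would
corrupt group means; callers far above that regime can clamp explicitly to
1 − 1/(2·n_sites). Nominal coverage is mean raw reads per panel site in
simulation mode and sequenced bases ÷ genome size (default 3,101,804,739,
the hs37 primary assembly) in real-data mode; the mode is labelled in every
summary. Duplicate status is consumed as a per-read/per-site flag provided
by the producer; the package does not re-detect duplicates.

## Imputation

Genotype likelihoods at a site with r ref and a alt filtered reads and
miscall rate ε are L(hom-ref) = (1−ε)^r ε^a, L(het) = 0.5^(r+a),
L(hom-alt) = ε^r (1−ε)^a; the shared binomial coefficient cancels on
normalisation. The vectorised path evaluates them in log space and rescales
each site to a maximum of 1, which posteriors are invariant to.

The diploid Li–Stephens HMM is exact: hidden state = ordered pair of panel
haplotypes (H² states over the reduced panel), uniform initial distribution,
per-interval transitions in which each copying process independently
switches to a uniform haplotype (including its current one) with probability
`recomb_scale · genetic_dist`, and emissions that mix the three genotypes
implied by the copied allele pair under independent `copy_error` flips.
Posteriors come from a scaled forward–backward pass; the factorised
transition (apply the one-chain operator along each state axis) makes a pass
O(M·H²) time, and the cached per-site emission tables make memory O(M·H²).
At the default desk scale (H = 38 after hold-out, M = 2000) a sample imputes
in well under a second; the exact formulation was chosen over sampling or
state-space-compression approximations because it is oracle-testable by
exhaustive path enumeration on small instances.

Defaults `recomb_scale = 0.001` and `copy_error = 0.001` match the
generative defaults of the truth simulator; both are exposed on the CLI.
The switch target is uniform rather than frequency-weighted — the simplest
published variant, and the one the enumeration oracle checks exactly.

Calls are the posterior argmax with deterministic tie preference
hom-ref < het < hom-alt; a site is low-confidence exactly when its best
posterior is ≤ 0.9 (strict: 0.9 itself fails), and low-confidence sites are
removed before any concordance comparison, with the removal count reported.

## Non-reference concordance

NRC = matches ÷ (intersection − both-hom-ref sites), computed after
excluding missing/filtered sites from either call set. An empty denominator
yields an explicitly undefined result, never 0. The AF stratification folds
panel alternate-allele frequencies to minor-allele frequencies by default
(panel AF can exceed 0.5); default bin edges are the log-spaced
{0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5}, fully configurable. Bins are
half-open [lo, hi) with the top edge inclusive so MAF = 0.5 is not dropped;
sites outside the binned range count toward the overall figures only. The
study driver reports both the mean of per-sample bin NRCs (default, the
conventional cohort summary) and the pooled ratio of summed counts.

## Group comparison and study driver

Group summaries use the sample SD (n−1). Welch's t-test is two-sided, with
Welch–Satterthwaite degrees of freedom computed from the closed form; the
degenerate all-constant case returns t = 0, p = 1 for equal means and an
infinite t otherwise. No multiple-testing correction is applied — the driver
reports a small number of pre-specified unadjusted tests.

`run_experiment` runs arms that share, per sample index, the same truth
individual and read-simulation stream, so arm contrasts isolate the
configuration difference (a paired design). Default study conditions: one
40-haplotype × 2000-site neutral-SFS panel (`ld_strength` 0.7), 20 samples
per arm at nominal coverage 1.0×, arms differing only in duplicate rate
0.0027 vs 0.055. At this scale the whole study runs in tens of seconds on
one CPU; the coverage identities are instead checked on 100,000-site
panels, where binomial error on f_covered is ~0.002.

The population-regime contrast used in testing defines a high-diversity
regime (`sfs_exponent` 0.7, `ld_strength` 0.4) and a high-LD regime
(`sfs_exponent` 1.3, `ld_strength` 0.9): the former makes rare sites less
singleton-dominated (their carriers are taggable), the latter makes
haplotype tracking easier. The expected pattern — rare-bin NRC higher under
diversity, common-bin NRC higher under LD — emerges from the generator, but
it is model-dependent and asserted only directionally on means over paired
replicates.

## Known limitations

* The panel generator's LD is first-order (carrier-set copying); long-range
  haplotype structure is absent, so absolute NRC values at a given coverage
  are not calibrated to any real panel — only orderings and identities are.
* The exact H²-state HMM is a desk-scale tool; genome-scale panels
  (thousands of haplotypes, millions of sites) would need chunking and
  state-space compression that are out of scope here.
* The mpileup reader assumes duplicates were removed upstream and therefore
  cannot recover duplicate tallies from that format; the TSV pileup dialect
  exists precisely to preserve them.
* Phasing quality, dosage r², indels and multi-sample joint imputation are
  out of scope.
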