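"""Synthetic haplotype panels, truth individuals, and low-pass pileups.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without any download:

* a biallelic-SNP haplotype reference panel whose allele frequencies follow
  a configurable site-frequency spectrum (neutral ``P(i) ∝ 1/i`` by default)
  and whose adjacent sites carry tunable linkage disequilibrium through a
  carrier-set copying construction;
* a diploid truth individual built as a recombinant mosaic of panel
  haplotypes (the generative mirror of the haplotype-copying model used for
  imputation), whose two initial source rows are recorded for leave-one-out
  hold-out;
* per-site read pileups at a target nominal coverage, with a tunable
  duplicate-read process, overdispersion, sequencing base errors and
  Phred-scaled base qualities.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ALT, OTHER, REF, PileupSet, RawReadTally, ReadBundle, SiteList

_BASES = np.array(list("ACGT"), dtype=object)


def _rng(seed, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypePanel:
    """Phased biallelic-SNP reference panel.

    ``alleles`` is a {0,1} matrix with one row per haplotype and one column
    per site; ``genetic_dist`` holds per-adjacent-interval recombination
    distances on a unitless probability scale (the per-interval switch
    probability of the copying model is ``recomb_scale * genetic_dist``).
    """

    sites: SiteList
    alleles: np.ndarray
    genetic_dist: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, np.uint8)
        object.__setattr__(self, "alleles", a)
        object.__setattr__(self, "genetic_dist",
                           np.asarray(self.genetic_dist, float))
        H, M = a.shape
        if H < 4 or H % 2:
            raise ValueError("panel needs an even number of haplotypes >= 4")
        if M != len(self.sites):
            raise ValueError("allele matrix does not match site list")
        if self.genetic_dist.shape != (M - 1,):
            raise ValueError("genetic_dist needs one entry per adjacent interval")
        if np.any((a != 0) & (a != 1)):
            raise ValueError("alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def af(self) -> np.ndarray:
        """Per-site alternate-allele frequency (recomputed from the matrix)."""
        return self.alleles.mean(axis=0)

    def reduced_alleles(self, held_out: Sequence[int]) -> np.ndarray:
        """Allele matrix with the held-out haplotype rows removed."""
        held = list(held_out)
        if any(h < 0 or h >= self.n_haplotypes for h in held):
            raise ValueError("held-out haplotype index out of range")
        keep = np.setdiff1d(np.arange(self.n_haplotypes), held)
        if len(keep) < 2:
            raise ValueError("reduced panel has fewer than 2 haplotypes")
        return self.alleles[keep]


def _sfs_counts(n_hap: int, n_sites: int, sfs_exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw derived-allele counts in [1, n_hap-1] with P(i) ∝ i**-exponent."""
    i = np.arange(1, n_hap)
    w = i.astype(float) ** -sfs_exponent
    w /= w.sum()
    return rng.choice(i, size=n_sites, p=w)


def generate_panel(n_haplotypes: int = 40, n_sites: int = 2000, *,
                   sfs_exponent: float = 1.0, ld_strength: float = 0.7,
                   chrom: str = "1", site_spacing: int = 1000,
                   seed=None, rng: np.random.Generator | None = None,
                   ) -> HaplotypePanel:
    """Generate a haplotype panel with a realistic SFS and tunable LD.

    Allele counts per site are drawn from ``P(count=i) ∝ i**-sfs_exponent``
    (``1.0`` = the neutral spectrum), so no site is monomorphic by
    construction.  Linkage is induced by a carrier-set copying rule: with
    probability ``ld_strength`` a site's carrier set is derived from the
    previous site's carriers (resized to the drawn count), otherwise it is a
    fresh uniform subset.  ``ld_strength=0`` gives independent sites;
    values near 1 give near-identical adjacent carrier sets.
    """
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 4")
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if not 0.0 <= ld_strength <= 1.0:
        raise ValueError("ld_strength must be in [0, 1]")
    rng = _rng(seed, rng)
    H, M = n_haplotypes, n_sites
    counts = _sfs_counts(H, M, sfs_exponent, rng)
    alleles = np.zeros((H, M), np.uint8)
    all_rows = np.arange(H)
    prev: np.ndarray | None = None
    for j in range(M):
        c = int(counts[j])
        if prev is not None and rng.random() < ld_strength:
            carriers = prev
            if len(carriers) > c:
                carriers = rng.choice(carriers, size=c, replace=False)
            elif len(carriers) < c:
                non = np.setdiff1d(all_rows, carriers, assume_unique=False)
                extra = rng.choice(non, size=c - len(carriers), replace=False)
                carriers = np.concatenate([carriers, extra])
        else:
            carriers = rng.choice(all_rows, size=c, replace=False)
        alleles[carriers, j] = 1
        prev = carriers
    refs = rng.integers(0, 4, size=M)
    alts = (refs + rng.integers(1, 4, size=M)) % 4
    sites = SiteList(
        chrom=np.full(M, chrom, object),
        pos=(np.arange(M, dtype=np.int64) + 1) * site_spacing,
        ref=_BASES[refs], alt=_BASES[alts])
    return HaplotypePanel(sites=sites, alleles=alleles,
                          genetic_dist=np.ones(M - 1))


# ---------------------------------------------------------------------------
# truth individual
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthIndividual:
    """A diploid individual whose haplotypes are recombinant panel mosaics.

    ``hap_indices`` are the two panel rows used to initialise the mosaics;
    they are held out of the panel at imputation time.  ``mosaic_paths``
    records the copying source row at every site; ``haplotypes`` the copied
    (and possibly mutated) alleles; ``genotypes`` their per-site sum.
    """

    hap_indices: tuple[int, int]
    mosaic_paths: np.ndarray   # (2, M) int
    haplotypes: np.ndarray     # (2, M) uint8
    genotypes: np.ndarray      # (M,) int in {0,1,2}
    n_switches: tuple[int, int] = (0, 0)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]


def simulate_individual(panel: HaplotypePanel, recomb_rate: float = 0.001,
                        mutation_rate: float = 0.001, *, seed=None,
                        rng: np.random.Generator | None = None,
                        ) -> TruthIndividual:
    """Simulate a truth individual by haplotype copying from the panel.

    Each of the two haplotypes starts on a distinct uniformly chosen panel
    row, switches to a uniformly chosen row with probability ``recomb_rate``
    per adjacent-site interval, and flips the copied allele with probability
    ``mutation_rate`` per site.
    """
    if not 0 <= recomb_rate < 1 or not 0 <= mutation_rate < 1:
        raise ValueError("recomb_rate and mutation_rate must be in [0, 1)")
    if panel.n_haplotypes < 4:
        raise ValueError("panel too small to hold out two haplotypes")
    rng = _rng(seed, rng)
    H, M = panel.alleles.shape
    start = rng.choice(H, size=2, replace=False)
    paths = np.empty((2, M), np.int64)
    switches = [0, 0]
    for h in range(2):
        path = np.empty(M, np.int64)
        path[0] = start[h]
        ev = rng.random(M - 1) < recomb_rate
        targets = rng.integers(0, H, size=M - 1)
        cur = start[h]
        for j in range(1, M):
            if ev[j - 1]:
                cur = targets[j - 1]
                switches[h] += 1
            path[j] = cur
        paths[h] = path
    haps = panel.alleles[paths, np.arange(M)].astype(np.uint8)
    if mutation_rate > 0:
        flips = rng.random((2, M)) < mutation_rate
        haps = np.where(flips, 1 - haps, haps).astype(np.uint8)
    return TruthIndividual(
        hap_indices=(int(start[0]), int(start[1])),
        mosaic_paths=paths, haplotypes=haps,
        genotypes=haps.sum(axis=0).astype(np.int64),
        n_switches=(switches[0], switches[1]))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation settings for one sample.

    nominal_coverage
        Mean raw reads per panel site (the simulation-mode analogue of
        sequenced bases / genome size).
    dup_rate
        Probability each raw read is a duplicate of another read at its site.
    overdispersion
        Extra-Poisson dispersion φ of per-site raw read counts
        (variance = λ + φλ²; 0 gives Poisson).
    base_error
        Per-base miscall probability ε.
    bq_distribution
        Discrete distribution over Phred base qualities, as
        ``((phred, weight), ...)``; default all Q30.  A mixture with mass at
        Q12 exercises the BQ>=13 coverage filter.
    """

    nominal_coverage: float = 0.8
    dup_rate: float = 0.0
    overdispersion: float = 0.0
    base_error: float = 0.002
    bq_distribution: tuple[tuple[int, float], ...] = ((30, 1.0),)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nominal_coverage <= 0:
            raise ValueError("nominal_coverage must be > 0")
        if not 0 <= self.dup_rate < 1:
            raise ValueError("dup_rate must be in [0, 1)")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        w = np.array([w for _, w in self.bq_distribution], float)
        if len(w) == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("bq_distribution weights must be >= 0 and sum to 1")
        if any(q < 0 for q, _ in self.bq_distribution):
            raise ValueError("Phred qualities must be >= 0")


def _raw_depths(cfg: ReadSimConfig, n_sites: int,
                rng: np.random.Generator) -> np.ndarray:
    lam = cfg.nominal_coverage
    if cfg.overdispersion == 0:
        return rng.poisson(lam, size=n_sites)
    # negative binomial with mean λ and variance λ + φλ²
    phi = cfg.overdispersion
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * lam)
    return rng.negative_binomial(n, p, size=n_sites)


def simulate_pileup(individual: TruthIndividual, panel: HaplotypePanel,
                    config: ReadSimConfig, *, min_base_quality: int = 13,
                    keep_reads: bool = False,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[PileupSet, RawReadTally]:
    """Simulate per-site pileups for one individual.

    Per site the raw read count is Poisson (or negative-binomial under
    overdispersion) with mean ``nominal_coverage``.  Each raw read is
    independently a duplicate with probability ``dup_rate``; a duplicate
    replicates the allele and base quality of a previously drawn unique read
    at its site (drawing fresh when none exists) and is excluded from the
    filtered counts.  Unique reads sample one of the individual's two
    haplotypes with equal probability, miscall the allele with probability
    ``base_error``, carry a Phred quality from ``bq_distribution``, and are
    counted only when that quality reaches ``min_base_quality``.
    """
    if individual.n_sites != panel.n_sites:
        raise ValueError("individual and panel site lists differ")
    rng = _rng(config.seed, rng)
    M = panel.n_sites
    raw = _raw_depths(config, M, rng)
    total_raw = int(raw.sum())
    site_of_read = np.repeat(np.arange(M), raw)
    # shared-uniform duplicate flags: with a common rng state across
    # configurations, the duplicate sets are nested in dup_rate
    is_dup = rng.random(total_raw) < config.dup_rate
    dup_count = np.bincount(site_of_read[is_dup], minlength=M).astype(np.int64)
    uniq_sites = site_of_read[~is_dup]
    n_uniq = len(uniq_sites)

    # unique reads: true allele, sequencing error, quality
    hap_pick = rng.integers(0, 2, size=n_uniq)
    true_allele = individual.haplotypes[hap_pick, uniq_sites]
    err = rng.random(n_uniq) < config.base_error
    obs_alt = np.where(err, 1 - true_allele, true_allele).astype(np.int64)
    quals = np.array([q for q, _ in config.bq_distribution])
    weights = np.array([w for _, w in config.bq_distribution], float)
    weights = weights / weights.sum()
    phred = rng.choice(quals, size=n_uniq, p=weights)
    passing = phred >= min_base_quality

    alt_count = np.bincount(uniq_sites[passing & (obs_alt == 1)],
                            minlength=M).astype(np.int64)
    ref_count = np.bincount(uniq_sites[passing & (obs_alt == 0)],
                            minlength=M).astype(np.int64)
    other_count = np.zeros(M, np.int64)

    reads = None
    if keep_reads:
        reads = _per_read_detail(M, uniq_sites, obs_alt, phred, dup_count, rng,
                                 config)
    pileups = PileupSet(panel.sites, ref_count, alt_count, other_count,
                        raw, dup_count, min_base_quality=min_base_quality,
                        reads=reads)
    return pileups, RawReadTally(total_raw, int(dup_count.sum()))


def _per_read_detail(M, uniq_sites, obs_alt, phred, dup_count, rng, config):
    """Assemble per-site read bundles, materialising duplicate copies."""
    reads = []
    order = np.argsort(uniq_sites, kind="stable")
    u_site = uniq_sites[order]
    u_alt = obs_alt[order]
    u_phred = phred[order]
    bounds = np.searchsorted(u_site, np.arange(M + 1))
    quals = np.array([q for q, _ in config.bq_distribution])
    weights = np.array([w for _, w in config.bq_distribution], float)
    weights = weights / weights.sum()
    for j in range(M):
        lo, hi = bounds[j], bounds[j + 1]
        a = np.where(u_alt[lo:hi] == 1, ALT, REF)
        q = u_phred[lo:hi].copy()
        d = np.zeros(hi - lo, bool)
        nd = int(dup_count[j])
        if nd:
            if hi > lo:
                src = rng.integers(0, hi - lo, size=nd)
                da, dq = a[src], q[src]
            else:  # duplicate with no unique read to copy: draw fresh
                da = rng.integers(0, 2, size=nd)
                da = np.where(da == 1, ALT, REF)
                dq = rng.choice(quals, size=nd, p=weights)
            a = np.concatenate([a, da])
            q = np.concatenate([q, dq])
            d = np.concatenate([d, np.ones(nd, bool)])
        reads.append(ReadBundle(allele=a.astype(np.int64),
                                phred=q.astype(np.int64), is_dup=d))
    return reads
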