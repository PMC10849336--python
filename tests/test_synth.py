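"""Generator tests: SFS realism, LD control, mosaic copying, read process."""

import numpy as np
import pytest

from lpimpute import (
    ReadSimConfig,
    generate_panel,
    simulate_individual,
    simulate_pileup,
)


class TestGeneratePanel:
    def test_seeded_determinism(self):
        a = generate_panel(4, 10, seed=7)
        b = generate_panel(4, 10, seed=7)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.sites.pos, b.sites.pos)
        c = generate_panel(4, 10, seed=8)
        assert not np.array_equal(a.alleles, c.alleles)

    def test_every_site_polymorphic(self, small_panel):
        counts = small_panel.alleles.sum(axis=0)
        assert counts.min() >= 1
        assert counts.max() <= small_panel.n_haplotypes - 1

    def test_af_is_column_mean(self, small_panel):
        assert np.allclose(small_panel.af,
                           small_panel.alleles.mean(axis=0), atol=1e-12)

    def test_rare_fraction_matches_neutral_spectrum(self):
        # P(count=i) ∝ 1/i on [1, 99]; mass of AF < 0.05 (counts 1..4) is
        # (1 + 1/2 + 1/3 + 1/4) / H_99
        n_hap, n_sites = 100, 5000
        harmonic = np.sum(1.0 / np.arange(1, n_hap))
        expected = np.sum(1.0 / np.arange(1, 5)) / harmonic
        panel = generate_panel(n_hap, n_sites, seed=3)
        observed = float(np.mean(panel.af < 0.05))
        sigma = np.sqrt(expected * (1 - expected) / n_sites)
        assert abs(observed - expected) < 3 * sigma

    def test_ld_strength_is_monotone_in_adjacent_correlation(self):
        def mean_corr(ld):
            panel = generate_panel(60, 1500, ld_strength=ld, seed=5)
            x = panel.alleles.astype(float)
            x = x - x.mean(axis=0)
            num = (x[:, :-1] * x[:, 1:]).sum(axis=0)
            den = np.sqrt((x[:, :-1] ** 2).sum(axis=0)
                          * (x[:, 1:] ** 2).sum(axis=0))
            return float(np.abs(num / den).mean())

        corrs = [mean_corr(ld) for ld in (0.1, 0.5, 0.9)]
        assert corrs[0] < corrs[1] < corrs[2]

    @pytest.mark.parametrize("n_hap,n_sites", [(3, 10), (5, 10), (4, 1), (2, 5)])
    def test_invalid_sizes_raise(self, n_hap, n_sites):
        with pytest.raises(ValueError):
            generate_panel(n_hap, n_sites, seed=0)


class TestSimulateIndividual:
    def test_no_recombination_copies_single_rows(self, small_panel):
        ind = simulate_individual(small_panel, recomb_rate=0.0,
                                  mutation_rate=0.0, seed=1)
        for h in range(2):
            row = ind.hap_indices[h]
            assert np.all(ind.mosaic_paths[h] == row)
            assert np.array_equal(ind.haplotypes[h], small_panel.alleles[row])
        assert np.array_equal(ind.genotypes, ind.haplotypes.sum(axis=0))

    def test_copy_fidelity_without_mutation(self, small_panel):
        ind = simulate_individual(small_panel, recomb_rate=0.05,
                                  mutation_rate=0.0, seed=2)
        M = small_panel.n_sites
        for h in range(2):
            src = small_panel.alleles[ind.mosaic_paths[h], np.arange(M)]
            assert np.array_equal(ind.haplotypes[h], src)

    def test_paths_change_only_at_switches(self, small_panel):
        ind = simulate_individual(small_panel, recomb_rate=0.01,
                                  mutation_rate=0.0, seed=3)
        for h in range(2):
            changes = int(np.sum(np.diff(ind.mosaic_paths[h]) != 0))
            assert changes <= ind.n_switches[h]

    def test_switch_count_binomial(self):
        panel = generate_panel(8, 10_001, ld_strength=0.0, seed=4)
        ind = simulate_individual(panel, recomb_rate=0.5, mutation_rate=0.0,
                                  seed=5)
        n, p = 10_000, 0.5
        sigma = np.sqrt(n * p * (1 - p))
        for h in range(2):
            assert abs(ind.n_switches[h] - n * p) < 3 * sigma

    def test_bad_rates_raise(self, small_panel):
        with pytest.raises(ValueError):
            simulate_individual(small_panel, recomb_rate=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_individual(small_panel, mutation_rate=-0.1, seed=0)


class TestSimulatePileup:
    def test_seeded_determinism(self, small_panel):
        ind = simulate_individual(small_panel, seed=1)
        cfg = ReadSimConfig(nominal_coverage=0.8, dup_rate=0.02, seed=9)
        p1, t1 = simulate_pileup(ind, small_panel, cfg)
        p2, t2 = simulate_pileup(ind, small_panel, cfg)
        for attr in ("ref_count", "alt_count", "raw_depth", "dup_count"):
            assert np.array_equal(getattr(p1, attr), getattr(p2, attr))
        assert t1 == t2

    def test_no_duplicates_when_rate_zero(self, small_panel, default_config):
        ind = simulate_individual(small_panel, seed=1)
        pile, tally = simulate_pileup(ind, small_panel, default_config,
                                      rng=np.random.default_rng(2))
        assert tally.duplicate_reads == 0
        assert pile.dup_count.sum() == 0

    def test_homref_sites_have_no_alt_reads_without_errors(self, small_panel):
        ind = simulate_individual(small_panel, seed=1)
        cfg = ReadSimConfig(nominal_coverage=2.0, base_error=0.0)
        pile, _ = simulate_pileup(ind, small_panel, cfg,
                                  rng=np.random.default_rng(3))
        homref = ind.genotypes == 0
        assert pile.alt_count[homref].sum() == 0

    def test_read_conservation(self, small_panel):
        ind = simulate_individual(small_panel, seed=1)
        cfg = ReadSimConfig(nominal_coverage=1.5, dup_rate=0.1)
        pile, tally = simulate_pileup(ind, small_panel, cfg,
                                      rng=np.random.default_rng(4))
        assert np.all(pile.unique_depth + pile.dup_count == pile.raw_depth)
        assert tally.total_reads == pile.raw_depth.sum()
        assert tally.duplicate_reads == pile.dup_count.sum()

    def test_unique_depth_is_thinned_poisson(self):
        # with dup_rate d the unique depth per site is Poisson(λ(1-d))
        lam, d, n_sites = 1.0, 0.055, 100_000
        panel = generate_panel(8, n_sites, ld_strength=0.0, seed=6)
        ind = simulate_individual(panel, seed=7)
        cfg = ReadSimConfig(nominal_coverage=lam, dup_rate=d)
        pile, _ = simulate_pileup(ind, panel, cfg,
                                  rng=np.random.default_rng(8))
        mean_u = pile.unique_depth.mean()
        target = lam * (1 - d)
        assert abs(mean_u - target) < 3 * np.sqrt(target / n_sites)
        assert abs(pile.unique_depth.var() - target) < 0.02

    def test_fraction_covered_matches_poisson_void(self):
        lam, n_sites = 1.0, 100_000
        panel = generate_panel(8, n_sites, ld_strength=0.0, seed=9)
        ind = simulate_individual(panel, seed=10)
        pile, _ = simulate_pileup(ind, panel,
                                  ReadSimConfig(nominal_coverage=lam),
                                  rng=np.random.default_rng(11))
        expected = 1.0 - np.exp(-lam)
        observed = np.mean(pile.passing_depth > 0)
        sigma = np.sqrt(expected * (1 - expected) / n_sites)
        assert abs(observed - expected) < 3 * sigma

    def test_low_quality_bases_are_not_counted(self, small_panel):
        ind = simulate_individual(small_panel, seed=1)
        cfg = ReadSimConfig(nominal_coverage=2.0,
                            bq_distribution=((12, 1.0),))
        pile, _ = simulate_pileup(ind, small_panel, cfg,
                                  rng=np.random.default_rng(5))
        assert pile.passing_depth.sum() == 0
        assert pile.raw_depth.sum() > 0

    @pytest.mark.parametrize("kwargs", [
        dict(nominal_coverage=0.0),
        dict(dup_rate=1.0),
        dict(base_error=0.5),
        dict(overdispersion=-1.0),
        dict(bq_distribution=((30, 0.5),)),
    ])
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            ReadSimConfig(**kwargs)
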