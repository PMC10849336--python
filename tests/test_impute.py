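"""Genotype likelihoods, the diploid copying HMM, and the confidence filter."""

import numpy as np
import pytest

from lpimpute import (
    DiploidLiStephens,
    GenotypePosteriors,
    HmmParams,
    filter_posteriors,
    genotype_likelihoods,
    impute_sample,
    likelihoods_from_counts,
    simulate_individual,
)
from lpimpute.synth import HaplotypePanel
from oracles import enumerate_diploid_posteriors


class TestGenotypeLikelihoods:
    def test_zero_depth_is_uninformative(self):
        assert np.allclose(genotype_likelihoods(0, 0, 0.01), [1.0, 1.0, 1.0])

    def test_two_ref_reads(self):
        lik = genotype_likelihoods(2, 0, 0.01)
        assert np.allclose(lik, [0.9801, 0.25, 0.0001], atol=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.01, 0.2, 0.49])
    def test_mixed_reads_favour_het(self, eps):
        lik = genotype_likelihoods(1, 1, eps)
        assert lik[1] > lik[0] and lik[1] > lik[2]

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            genotype_likelihoods(-1, 0, 0.01)

    def test_deep_sites_do_not_underflow_when_rescaled(self):
        lik = likelihoods_from_counts(np.array([5000]), np.array([4000]), 0.01)
        assert np.all(np.isfinite(lik))
        assert lik.max() == 1.0

    def test_zero_error_edge(self):
        lik = genotype_likelihoods(3, 0, 0.0)
        assert np.allclose(lik, [1.0, 0.125, 0.0])


def _random_instance(rng):
    H = rng.integers(2, 6)
    M = rng.integers(2, 5)
    alleles = rng.integers(0, 2, size=(H, M))
    # ensure at least one 0 and one 1 somewhere so the instance is not trivial
    alleles[0, 0] = 0
    alleles[-1, -1] = 1
    lik = rng.uniform(0.01, 1.0, size=(M, 3))
    if rng.random() < 0.5:
        lik[rng.integers(0, M)] = 1.0  # a zero-depth site
    gdist = rng.uniform(0.5, 2.0, size=M - 1)
    params = HmmParams(recomb_scale=float(rng.uniform(0.001, 0.3)),
                       copy_error=float(rng.uniform(0.001, 0.3)))
    return alleles, gdist, lik, params


class TestForwardBackward:
    def test_matches_enumeration_on_fixed_instance(self, tiny_panel):
        lik = np.array([[0.9, 0.3, 0.01], [1.0, 1.0, 1.0], [0.05, 0.8, 0.4]])
        params = HmmParams(recomb_scale=0.05, copy_error=0.01)
        model = DiploidLiStephens(tiny_panel.alleles, tiny_panel.genetic_dist,
                                  params)
        got = model.posteriors(lik)
        want = enumerate_diploid_posteriors(
            tiny_panel.alleles, tiny_panel.genetic_dist, lik,
            params.recomb_scale, params.copy_error)
        assert np.allclose(got, want, atol=1e-10)

    def test_matches_enumeration_randomised(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            alleles, gdist, lik, params = _random_instance(rng)
            got = DiploidLiStephens(alleles, gdist, params).posteriors(lik)
            want = enumerate_diploid_posteriors(
                alleles, gdist, lik, params.recomb_scale, params.copy_error)
            assert np.allclose(got, want, atol=1e-8)

    def test_posteriors_normalised_and_scale_invariant(self, tiny_panel):
        rng = np.random.default_rng(1)
        lik = rng.uniform(0.01, 1.0, size=(3, 3))
        model = DiploidLiStephens(tiny_panel.alleles, tiny_panel.genetic_dist)
        p1 = model.posteriors(lik)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-12)
        scaled = lik * rng.uniform(0.5, 100.0, size=(3, 1))
        p2 = model.posteriors(scaled)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_deep_coverage_recovers_truth(self, small_panel):
        ind = simulate_individual(small_panel, 0.001, 0.001, seed=3)
        depth = 50
        ref = np.where(ind.genotypes == 0, depth,
                       np.where(ind.genotypes == 1, depth // 2, 0))
        alt = depth - ref
        lik = likelihoods_from_counts(ref, alt, 0.0)
        post = impute_sample(lik, small_panel, ind.hap_indices)
        assert np.array_equal(post.call, ind.genotypes)

    def test_identical_panel_zero_reads(self):
        # all haplotypes carry the same pattern; with no reads the posterior
        # concentrates on the genotype that pattern implies
        from lpimpute import SiteList
        sites = SiteList.from_records(
            [("1", 100, "A", "C"), ("1", 200, "G", "T")])
        alleles = np.tile(np.array([[1, 0]], np.uint8), (4, 1))
        panel = HaplotypePanel(sites=sites, alleles=alleles,
                               genetic_dist=np.ones(1))
        model = DiploidLiStephens(panel.alleles, panel.genetic_dist,
                                  HmmParams(recomb_scale=0.001,
                                            copy_error=1e-6))
        post = model.posteriors(np.ones((2, 3)))
        assert post[0, 2] > 0.999   # both copies carry the alt
        assert post[1, 0] > 0.999   # both copies carry the ref

    def test_leave_one_out_ignores_held_rows(self, small_panel):
        ind = simulate_individual(small_panel, seed=4)
        rng = np.random.default_rng(5)
        lik = rng.uniform(0.01, 1.0, size=(small_panel.n_sites, 3))
        p1 = impute_sample(lik, small_panel, ind.hap_indices)
        corrupted = small_panel.alleles.copy()
        for h in ind.hap_indices:
            corrupted[h] = rng.integers(0, 2, size=small_panel.n_sites)
        panel2 = HaplotypePanel(sites=small_panel.sites, alleles=corrupted,
                                genetic_dist=small_panel.genetic_dist)
        p2 = impute_sample(lik, panel2, ind.hap_indices)
        assert np.array_equal(p1.probs, p2.probs)

    def test_reduced_panel_too_small_raises(self, tiny_panel):
        with pytest.raises(ValueError):
            impute_sample(np.ones((3, 3)), tiny_panel, [0, 1, 2])

    def test_bad_likelihood_shape_raises(self, tiny_panel):
        model = DiploidLiStephens(tiny_panel.alleles, tiny_panel.genetic_dist)
        with pytest.raises(ValueError):
            model.posteriors(np.ones((5, 3)))


class TestConfidenceFilter:
    def test_strictly_greater_than_threshold(self):
        probs = np.array([
            [0.95, 0.04, 0.01],   # retained
            [0.9, 0.05, 0.05],    # removed: 0.9 is not > 0.9
            [0.901, 0.05, 0.049], # retained
        ])
        post = GenotypePosteriors.from_probs(probs)
        filt = filter_posteriors(post)
        assert filt.kept.tolist() == [True, False, True]
        assert filt.calls.tolist() == [0, -1, 0]
        assert filt.n_filtered == 1

    def test_survivor_hand_count(self):
        probs = np.array([
            [0.99, 0.01, 0.0],
            [0.5, 0.3, 0.2],
            [0.05, 0.92, 0.03],
            [0.33, 0.33, 0.34],
            [0.0, 0.02, 0.98],
        ])
        filt = filter_posteriors(GenotypePosteriors.from_probs(probs))
        assert filt.kept.sum() == 3
        assert filt.n_filtered == 2

    def test_low_confidence_flag_matches_threshold(self):
        probs = np.array([[0.9, 0.05, 0.05], [0.91, 0.05, 0.04]])
        post = GenotypePosteriors.from_probs(probs)
        assert post.low_confidence.tolist() == [True, False]

    def test_argmax_tie_prefers_lower_genotype(self):
        probs = np.array([[0.46, 0.46, 0.08], [0.08, 0.46, 0.46]])
        post = GenotypePosteriors.from_probs(probs)
        assert post.call.tolist() == [0, 1]
        assert post.low_confidence.all()

    def test_unnormalised_posteriors_rejected(self):
        with pytest.raises(ValueError):
            GenotypePosteriors.from_probs(np.array([[0.5, 0.1, 0.1]]))
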