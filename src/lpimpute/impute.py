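"""Leave-one-out genotype imputation with a diploid Li-Stephens HMM.

Pipeline: per-site binomial genotype likelihoods from filtered pileup counts
feed an exact diploid haplotype-copying HMM over the reference panel with
the sample's own two haplotypes removed.  The hidden state is an ordered
pair of panel haplotypes; each copying process independently switches to a
uniformly chosen haplotype with probability ``recomb_scale * genetic_dist``
per interval, and the copied allele pair emits the read data through a
per-allele copy-error parameter.  Posteriors are computed by a scaled
forward-backward pass and marginalised to the three genotypes; calls with no
posterior above 0.9 are flagged low-confidence and removed by the
downstream filter.

Complexity is O(M * H^2) per forward/backward pass after the standard
per-process factorisation of the transition; memory is O(M * H^2) for the
cached emission tables, which is comfortable at desk scale (H <= ~60).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PileupSet, SitePileup, as_pileup_set
from .synth import HaplotypePanel


@dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters.

    recomb_scale
        Expected switch probability per unit genetic distance (per interval
        with the default unit distances).
    copy_error
        Probability the copied panel allele mismatches the true haplotype
        allele (mutation/error parameter).
    """

    recomb_scale: float = 0.001
    copy_error: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.recomb_scale < 1.0:
            raise ValueError("recomb_scale must be in (0, 1)")
        if not 0.0 < self.copy_error < 1.0:
            raise ValueError("copy_error must be in (0, 1)")


class NumericalError(RuntimeError):
    """Forward mass vanished or became non-finite."""


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------

def genotype_likelihoods(ref_count: int, alt_count: int,
                         base_error: float) -> np.ndarray:
    """Read-data likelihoods (L_homref, L_het, L_homalt) at one site.

    With r ref and a alt reads and miscall probability ε:
    ``L_homref = (1-ε)^r ε^a``, ``L_het = 0.5^(r+a)``,
    ``L_homalt = ε^r (1-ε)^a`` (the shared binomial coefficient cancels on
    normalisation).  Zero depth gives the uninformative (1, 1, 1).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be >= 0")
    if not 0.0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    return likelihoods_from_counts(
        np.array([ref_count]), np.array([alt_count]), base_error,
        rescale=False)[0]


def likelihoods_from_counts(ref_count: np.ndarray, alt_count: np.ndarray,
                            base_error: float, rescale: bool = True,
                            ) -> np.ndarray:
    """Vectorised genotype likelihoods, (n_sites, 3).

    Computed in log space; with ``rescale`` each site is scaled to a maximum
    of 1 so deep sites do not underflow (posteriors are invariant to the
    per-site rescaling).
    """
    r = np.asarray(ref_count, float)
    a = np.asarray(alt_count, float)
    e = float(base_error)
    with np.errstate(divide="ignore"):
        log_e = np.log(e) if e > 0 else -np.inf
        log_1e = np.log1p(-e)
    def _mul(count, logp):
        # 0 * -inf must be 0 (no reads of that class observed)
        return np.where(count > 0, count * logp, 0.0)
    ll = np.stack([
        _mul(r, log_1e) + _mul(a, log_e),
        (r + a) * np.log(0.5),
        _mul(r, log_e) + _mul(a, log_1e),
    ], axis=1)
    if rescale:
        ll -= ll.max(axis=1, keepdims=True)
    return np.exp(ll)


def likelihoods_from_pileups(pileups: PileupSet | Sequence[SitePileup],
                             base_error: float = 0.002) -> np.ndarray:
    ps = as_pileup_set(pileups)
    return likelihoods_from_counts(ps.ref_count, ps.alt_count, base_error)


# ---------------------------------------------------------------------------
# posteriors container
# ---------------------------------------------------------------------------

#: deterministic argmax tie preference: hom-ref < het < hom-alt
GP_THRESHOLD = 0.9


@dataclass(frozen=True)
class GenotypePosteriors:
    """Per-site genotype posterior triples with calls and confidence flags.

    ``low_confidence`` is True exactly when no posterior exceeds the
    threshold (strictly); ties in the argmax resolve to the lowest genotype.
    """

    probs: np.ndarray          # (M, 3), rows sum to 1
    call: np.ndarray           # (M,) in {0,1,2}
    low_confidence: np.ndarray # (M,) bool
    threshold: float = GP_THRESHOLD

    @classmethod
    def from_probs(cls, probs: np.ndarray,
                   threshold: float = GP_THRESHOLD) -> "GenotypePosteriors":
        probs = np.asarray(probs, float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("posteriors must be (n_sites, 3)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior triples must sum to 1")
        call = np.argmax(probs, axis=1)
        low = probs.max(axis=1) <= threshold
        return cls(probs=probs, call=call, low_confidence=low,
                   threshold=threshold)

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class FilteredCalls:
    """Confidence-filtered call set: -1 marks removed sites."""

    calls: np.ndarray
    kept: np.ndarray
    n_filtered: int


def filter_posteriors(posteriors: GenotypePosteriors,
                      threshold: float = GP_THRESHOLD) -> FilteredCalls:
    """Drop calls whose best posterior does not strictly exceed the threshold.

    A maximum posterior exactly equal to the threshold is removed.
    """
    kept = posteriors.probs.max(axis=1) > threshold
    calls = np.where(kept, posteriors.call, -1)
    return FilteredCalls(calls=calls, kept=kept,
                         n_filtered=int((~kept).sum()))


# ---------------------------------------------------------------------------
# diploid Li-Stephens forward-backward
# ---------------------------------------------------------------------------

class DiploidLiStephens:
    """Exact diploid haplotype-copying HMM over a (reduced) panel.

    Parameters
    ----------
    alleles
        (H, M) {0,1} haplotype matrix — the panel *after* any hold-out.
    genetic_dist
        (M-1,) per-interval recombination distances.
    params
        Copying-model parameters.
    """

    def __init__(self, alleles: np.ndarray, genetic_dist: np.ndarray,
                 params: HmmParams = HmmParams()) -> None:
        self.alleles = np.asarray(alleles, np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise ValueError("need an (H, M) allele matrix with H >= 2")
        self.genetic_dist = np.asarray(genetic_dist, float)
        if self.genetic_dist.shape != (self.alleles.shape[1] - 1,):
            raise ValueError("genetic_dist length must be n_sites - 1")
        self.params = params
        e = params.copy_error
        # P(true haplotype allele = 1 | copied allele), per haplotype/site
        self.p_alt = np.where(self.alleles == 1, 1.0 - e, e)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def _switch_probs(self) -> np.ndarray:
        return np.minimum(self.params.recomb_scale * self.genetic_dist, 1.0)

    def _emissions(self, lik: np.ndarray) -> np.ndarray:
        """Per-site emission matrices E[j] over ordered haplotype pairs."""
        u = 1.0 - self.p_alt   # (H, M): P(true allele 0 | copied)
        v = self.p_alt
        L0, L1, L2 = lik[:, 0], lik[:, 1], lik[:, 2]
        # E[j,k,l] = L0 u_k u_l + L1 (u_k v_l + v_k u_l) + L2 v_k v_l
        uu = np.einsum("km,lm->mkl", u, u)
        vv = np.einsum("km,lm->mkl", v, v)
        uv = np.einsum("km,lm->mkl", u, v)
        E = (L0[:, None, None] * uu + L2[:, None, None] * vv
             + L1[:, None, None] * (uv + uv.transpose(0, 2, 1)))
        return E

    @staticmethod
    def _transition(F: np.ndarray, r: float, H: int) -> np.ndarray:
        """Apply the factorised pair transition to a (H, H) mass matrix."""
        F = (1.0 - r) * F + (r / H) * F.sum(axis=0, keepdims=True)
        F = (1.0 - r) * F + (r / H) * F.sum(axis=1, keepdims=True)
        return F

    def posteriors(self, likelihoods: np.ndarray) -> np.ndarray:
        """Genotype posterior triples, (M, 3), by scaled forward-backward."""
        lik = np.asarray(likelihoods, float)
        H, M = self.n_haplotypes, self.n_sites
        if lik.shape != (M, 3):
            raise ValueError(f"likelihoods must be ({M}, 3)")
        if np.any(lik < 0) or not np.all(np.isfinite(lik)):
            raise ValueError("likelihoods must be finite and non-negative")
        E = self._emissions(lik)
        rs = self._switch_probs()

        alpha = np.empty((M, H, H))
        scale = np.empty(M)
        a = E[0] / (H * H)
        scale[0] = a.sum()
        self._check(scale[0], 0)
        alpha[0] = a / scale[0]
        for j in range(1, M):
            f = self._transition(alpha[j - 1], rs[j - 1], H)
            a = f * E[j]
            scale[j] = a.sum()
            self._check(scale[j], j)
            alpha[j] = a / scale[j]

        post = np.empty((M, 3))
        beta = np.ones((H, H))
        u = 1.0 - self.p_alt
        v = self.p_alt
        for j in range(M - 1, -1, -1):
            gamma = alpha[j] * beta
            gamma /= gamma.sum()
            # P(g | data) = sum_state gamma * P(g | state, data_j), where
            # P(g | state, data_j) ∝ P(g | copied pair) * L_j(g)
            W = gamma / E[j]
            uj, vj = u[:, j], v[:, j]
            s0 = lik[j, 0] * (uj @ W @ uj)
            s2 = lik[j, 2] * (vj @ W @ vj)
            s1 = lik[j, 1] * (uj @ W @ vj + vj @ W @ uj)
            tot = s0 + s1 + s2
            post[j] = (s0 / tot, s1 / tot, s2 / tot)
            if j > 0:
                b = self._transition(E[j] * beta, rs[j - 1], H)
                beta = b / scale[j]
        return post

    @staticmethod
    def _check(mass: float, j: int) -> None:
        if not np.isfinite(mass) or mass <= 0:
            raise NumericalError(
                f"forward mass {mass!r} at site {j}: likelihoods may be "
                "degenerate (all-zero) or parameters pathological")


def impute_sample(likelihoods: np.ndarray, panel: HaplotypePanel,
                  held_out: Sequence[int], params: HmmParams = HmmParams(),
                  threshold: float = GP_THRESHOLD) -> GenotypePosteriors:
    """Impute one sample against the panel with its own haplotypes removed.

    ``held_out`` are the sample's two panel haplotype rows (leave-one-out
    discipline: the posteriors depend only on the remaining rows).
    """
    reduced = panel.reduced_alleles(held_out)
    model = DiploidLiStephens(reduced, panel.genetic_dist, params)
    probs = model.posteriors(likelihoods)
    return GenotypePosteriors.from_probs(probs, threshold=threshold)
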