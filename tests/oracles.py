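"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity from its definition by a different route
than the library (exhaustive path enumeration instead of forward-backward,
explicit per-site rule application instead of vectorised counting, textbook
closed forms instead of scipy's test object), so agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import stdtr


def enumerate_diploid_posteriors(alleles: np.ndarray, genetic_dist: np.ndarray,
                                 likelihoods: np.ndarray, recomb_scale: float,
                                 copy_error: float) -> np.ndarray:
    """Genotype posteriors by brute-force enumeration of all state paths.

    The hidden state is an ordered pair of haplotype rows; every one of the
    (H^2)^M paths is weighted by its prior (uniform start, per-interval
    independent-switch transitions) times the emissions along it.  Feasible
    only for tiny instances.
    """
    alleles = np.asarray(alleles)
    H, M = alleles.shape
    S = H * H
    e = copy_error

    # explicit pair-transition matrices (kron of the single-chain matrix)
    Ts = []
    for m in range(M - 1):
        r = min(recomb_scale * genetic_dist[m], 1.0)
        T1 = (1.0 - r) * np.eye(H) + (r / H) * np.ones((H, H))
        Ts.append(np.kron(T1, T1))

    # P(genotype | state) per site, by explicit flip convolution
    Pg = np.zeros((M, S, 3))
    for m in range(M):
        for k in range(H):
            for l in range(H):
                s = k * H + l
                pk = (1.0 - e) if alleles[k, m] == 1 else e
                pl = (1.0 - e) if alleles[l, m] == 1 else e
                Pg[m, s, 0] = (1 - pk) * (1 - pl)
                Pg[m, s, 1] = pk * (1 - pl) + (1 - pk) * pl
                Pg[m, s, 2] = pk * pl
    Em = np.einsum("msg,mg->ms", Pg, likelihoods)

    paths = np.indices((S,) * M).reshape(M, -1).T  # (S^M, M)
    w = np.full(len(paths), 1.0 / S)
    for m in range(1, M):
        w = w * Ts[m - 1][paths[:, m - 1], paths[:, m]]
    w_full = w.copy()
    for m in range(M):
        w_full = w_full * Em[m, paths[:, m]]

    post = np.zeros((M, 3))
    for j in range(M):
        q = w_full / Em[j, paths[:, j]]
        for g in range(3):
            post[j, g] = np.sum(q * Pg[j, paths[:, j], g] * likelihoods[j, g])
        post[j] /= post[j].sum()
    return post


def nrc_by_definition(imputed, truth):
    """Non-reference concordance applied site-by-site from its definition.

    Returns (n_intersect, n_both_homref, n_match_nonref, nrc or None).
    """
    n_intersect = n_both_homref = n_match = 0
    for i, t in zip(imputed, truth):
        if i < 0 or t < 0:       # missing/filtered on either side
            continue
        n_intersect += 1
        if i == 0 and t == 0:
            n_both_homref += 1
        elif i == t:
            n_match += 1
    denom = n_intersect - n_both_homref
    nrc = (n_match / denom) if denom > 0 else None
    return n_intersect, n_both_homref, n_match, nrc


def welch_by_formula(a, b):
    """Welch's t, Welch-Satterthwaite dof and two-sided p from the textbook
    closed forms."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    ma, mb = a.sum() / na, b.sum() / nb
    va = ((a - ma) ** 2).sum() / (na - 1)
    vb = ((b - mb) ** 2).sum() / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stdtr(dof, -abs(t))
    return t, dof, p
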