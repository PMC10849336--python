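"""Non-reference concordance (NRC) between an imputed call set and truth.

NRC is the genotype concordance over the intersection of called sites after
removing the sites at which *both* call sets are homozygous reference:

    NRC = n_match_nonref / (n_intersect - n_both_homref)

Sites missing or confidence-filtered in either call set are excluded from
the intersection first.  Because genotype calls against a large panel are
overwhelmingly homozygous reference, plain concordance is dominated by easy
sites; NRC scores only the sites that carry information about the sample's
non-reference alleles.  The ratio is undefined (reported as such, never as
0) when every intersecting site is both-hom-ref.

Per-allele-frequency-bin stratification uses half-open bins on the panel
allele frequency, folded to minor-allele frequency by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default minor-allele-frequency bin edges (log-spaced, standard for
#: imputation-accuracy reporting); fully configurable
DEFAULT_BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class BinConcordance:
    """NRC within one allele-frequency bin ``[lo, hi)``."""

    lo: float
    hi: float
    n_sites: int        # intersecting sites in the bin
    n_denom: int        # after removing both-hom-ref sites
    n_match: int        # matching non-double-hom-ref sites
    nrc: float | None


@dataclass(frozen=True)
class ConcordanceReport:
    """Overall (and optionally per-AF-bin) non-reference concordance."""

    n_intersect: int
    n_both_homref: int
    n_match_nonref: int
    nrc: float | None
    per_bin: tuple[BinConcordance, ...] | None = None
    n_excluded: int = 0  # sites dropped from the intersection (missing/filtered)

    @property
    def defined(self) -> bool:
        return self.nrc is not None

    @property
    def n_denom(self) -> int:
        return self.n_intersect - self.n_both_homref

    def summary(self) -> pd.DataFrame:
        rows = [{
            "bin": "overall", "lo": np.nan, "hi": np.nan,
            "n_sites": self.n_intersect, "n_denom": self.n_denom,
            "n_match": self.n_match_nonref,
            "nrc": np.nan if self.nrc is None else self.nrc,
        }]
        for b in self.per_bin or ():
            rows.append({
                "bin": f"[{b.lo:g},{b.hi:g})", "lo": b.lo, "hi": b.hi,
                "n_sites": b.n_sites, "n_denom": b.n_denom,
                "n_match": b.n_match,
                "nrc": np.nan if b.nrc is None else b.nrc,
            })
        return pd.DataFrame(rows)


def _validated(imputed, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    imp = np.asarray(imputed, np.int64)
    tru = np.asarray(truth, np.int64)
    if imp.shape != tru.shape:
        raise ValueError("call sets must align site-for-site")
    for arr in (imp, tru):
        if np.any((arr < -1) | (arr > 2)):
            raise ValueError("calls must be in {0,1,2} (-1 = missing)")
    mask = (imp >= 0) & (tru >= 0)
    return imp, tru, mask


def _counts(imp, tru, mask) -> tuple[int, int, int]:
    n_intersect = int(mask.sum())
    both0 = int(((imp == 0) & (tru == 0) & mask).sum())
    match = int(((imp == tru) & mask).sum()) - both0
    return n_intersect, both0, match


def nrc(imputed, truth) -> ConcordanceReport:
    """Overall non-reference concordance between two call sets.

    ``-1`` entries (missing or confidence-filtered calls) are excluded from
    the intersection on either side.
    """
    imp, tru, mask = _validated(imputed, truth)
    n_int, both0, match = _counts(imp, tru, mask)
    denom = n_int - both0
    return ConcordanceReport(
        n_intersect=n_int, n_both_homref=both0, n_match_nonref=match,
        nrc=(match / denom) if denom > 0 else None,
        n_excluded=int((~mask).sum()))


def fold_to_maf(af: np.ndarray) -> np.ndarray:
    """Fold alternate-allele frequencies to minor-allele frequencies."""
    af = np.asarray(af, float)
    return np.minimum(af, 1.0 - af)


def nrc_by_af_bin(imputed, truth, af, bin_edges=DEFAULT_BIN_EDGES,
                  fold_af: bool = True) -> ConcordanceReport:
    """NRC overall and stratified by panel allele frequency.

    Each site falls in exactly one half-open bin ``[lo, hi)`` (the last bin
    is closed on the right so the frequency exactly at the top edge is not
    dropped); sites outside the binned range contribute to the overall
    figures only.  Empty bins are reported with ``n=0`` and undefined NRC.
    """
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    imp, tru, mask = _validated(imputed, truth)
    freq = np.asarray(af, float)
    if freq.shape != imp.shape:
        raise ValueError("af must align with the call sets")
    if fold_af:
        freq = fold_to_maf(freq)
    n_int, both0, match = _counts(imp, tru, mask)
    denom = n_int - both0

    which = np.digitize(freq, edges, right=False) - 1  # bin index, -1 below
    which[freq == edges[-1]] = len(edges) - 2          # top edge inclusive
    bins = []
    for b in range(len(edges) - 1):
        sel = mask & (which == b)
        n_i, b0, m = _counts(imp, tru, sel)
        d = n_i - b0
        bins.append(BinConcordance(
            lo=float(edges[b]), hi=float(edges[b + 1]), n_sites=n_i,
            n_denom=d, n_match=m, nrc=(m / d) if d > 0 else None))
    return ConcordanceReport(
        n_intersect=n_int, n_both_homref=both0, n_match_nonref=match,
        nrc=(match / denom) if denom > 0 else None,
        per_bin=tuple(bins), n_excluded=int((~mask).sum()))
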