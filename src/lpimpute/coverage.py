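"""Effective coverage and duplication-rate summaries for one sample.

The central quantity is the *effective coverage*

    lambda_eff = -ln(1 - f_covered)

where ``f_covered`` is the fraction of reference-panel sites covered by at
least one deduplicated read of base quality >= 13.  Under uniform Poisson
coverage the per-site depth is Poisson(lambda) and the fraction of covered
sites is 1 - exp(-lambda), so lambda_eff recovers the true mean depth; any
departure from spatial uniformity (e.g. duplicate reads re-sampling the same
positions) lowers f_covered and hence lambda_eff relative to the nominal
coverage.  The ratio lambda_eff / nominal coverage is therefore a measure of
sequencing evenness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PileupSet, RawReadTally, SitePileup, as_pileup_set

#: genome size used to convert sequenced bases to nominal coverage in
#: real-data mode (hs37 primary assembly)
DEFAULT_GENOME_SIZE = 3_101_804_739


class CoverageSaturationError(ValueError):
    """Every panel site is covered: lambda_eff = -ln(0) is undefined.

    Callers working far above the low-pass regime may clamp ``f_covered``
    to ``1 - 1/(2 * n_sites)`` explicitly before retrying.
    """


@dataclass(frozen=True)
class CoverageSummary:
    """Coverage metrics for one sample.

    ``mode`` records how nominal coverage was obtained: ``"simulation"``
    (mean raw reads per panel site) or ``"real"`` (sequenced bases divided by
    genome size).
    """

    nominal_coverage: float
    f_covered: float
    lambda_eff: float
    eff_to_nominal_ratio: float
    dup_rate: float
    n_sites: int
    mode: str = "simulation"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "nominal_coverage": self.nominal_coverage,
            "f_covered": self.f_covered,
            "lambda_eff": self.lambda_eff,
            "eff_to_nominal_ratio": self.eff_to_nominal_ratio,
            "dup_rate": self.dup_rate,
            "n_sites": self.n_sites,
            "mode": self.mode,
        }])


def fraction_covered(pileups: PileupSet | Sequence[SitePileup],
                     min_base_quality: int = 13,
                     exclude_duplicates: bool = True) -> float:
    """Fraction of panel sites with >=1 read passing both filters.

    The pileup set must represent every panel site (zero-depth sites
    included) so the denominator is the full panel.
    """
    ps = as_pileup_set(pileups, min_base_quality=min_base_quality)
    if len(ps) == 0:
        raise ValueError("empty site list")
    counts = ps.counts_at_threshold(min_base_quality, exclude_duplicates)
    return float(np.count_nonzero(counts) / len(ps))


def effective_coverage(f_covered: float) -> float:
    """Effective coverage ``-ln(1 - f_covered)``.

    Raises :class:`CoverageSaturationError` at ``f_covered == 1``, where the
    quantity is infinite.
    """
    if not 0.0 <= f_covered <= 1.0:
        raise ValueError("f_covered must be in [0, 1]")
    if f_covered == 1.0:
        raise CoverageSaturationError(
            "all panel sites covered; effective coverage is unbounded")
    return -math.log1p(-f_covered)


def duplication_rate(raw_tally: RawReadTally) -> float:
    """Duplicate reads divided by total raw reads."""
    if raw_tally.total_reads < 1:
        raise ValueError("duplication rate undefined with zero reads")
    return raw_tally.duplicate_reads / raw_tally.total_reads


def summarize_coverage(pileups: PileupSet | Sequence[SitePileup],
                       raw_tally: RawReadTally | None = None,
                       n_sites: int | None = None, *,
                       min_base_quality: int = 13,
                       mode: str = "simulation",
                       genome_size: int = DEFAULT_GENOME_SIZE,
                       ) -> CoverageSummary:
    """Compose the full coverage summary for one sample.

    In ``"simulation"`` mode nominal coverage is mean raw reads per panel
    site; in ``"real"`` mode it is ``raw_tally.total_bases / genome_size``.
    """
    ps = as_pileup_set(pileups, min_base_quality=min_base_quality)
    if raw_tally is None:
        raw_tally = ps.tally()
    if n_sites is None:
        n_sites = len(ps)
    if n_sites < 1:
        raise ValueError("empty site list")
    if mode == "simulation":
        nominal = raw_tally.total_reads / n_sites
    elif mode == "real":
        if raw_tally.total_bases is None:
            raise ValueError("real mode requires raw_tally.total_bases")
        nominal = raw_tally.total_bases / genome_size
    else:
        raise ValueError(f"unknown mode {mode!r}")
    f_cov = fraction_covered(ps, min_base_quality)
    lam = effective_coverage(f_cov)
    ratio = lam / nominal if nominal > 0 else 0.0
    return CoverageSummary(
        nominal_coverage=float(nominal), f_covered=f_cov, lambda_eff=lam,
        eff_to_nominal_ratio=float(ratio),
        dup_rate=duplication_rate(raw_tally), n_sites=int(n_sites), mode=mode)
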