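"""Group summaries and the between-chemistry Welch comparison.

Reports follow the mean (standard deviation) convention; the two-group
comparison is an unpaired two-sample Welch's t-test (unequal variances)
with Welch-Satterthwaite degrees of freedom and a two-sided p-value.  No
multiple-testing correction is applied: the study design reports a small
number of pre-specified unadjusted tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def summarize(values: Sequence[float]) -> tuple[int, float, float]:
    """(n, mean, sample SD).  SD uses the n-1 denominator; NaN when n < 2."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty list")
    sd = float(x.std(ddof=1)) if x.size >= 2 else float("nan")
    return int(x.size), float(x.mean()), sd


@dataclass(frozen=True)
class GroupComparison:
    """Welch's t-test result between two groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    dof: float
    p_value: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group_a": self.label_a, "group_b": self.label_b,
            "n_a": self.n_a, "n_b": self.n_b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "t": self.t_statistic, "dof": self.dof, "p": self.p_value,
        }])


def welch_t(a: Sequence[float], b: Sequence[float],
            labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Unpaired two-sample Welch's t-test, two-sided.

    Degenerate input (both sample variances zero) yields t=0, p=1 when the
    group means are exactly equal and an infinite t with p=0 otherwise.
    """
    xa = np.asarray(a, float)
    xb = np.asarray(b, float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")
    na, ma, sa = summarize(xa)
    nb, mb, sb = summarize(xb)
    va, vb = sa * sa, sb * sb
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            t, p, dof = 0.0, 1.0, float(na + nb - 2)
        else:
            t = math.inf if ma > mb else -math.inf
            p, dof = 0.0, float(na + nb - 2)
    else:
        res = sps.ttest_ind(xa, xb, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        se2 = va / na + vb / nb
        dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return GroupComparison(
        label_a=labels[0], label_b=labels[1], n_a=na, n_b=nb,
        mean_a=ma, mean_b=mb, sd_a=sa, sd_b=sb,
        t_statistic=t, dof=float(dof), p_value=p)


# the full synthetic-study driver lives in lpimpute.experiment; re-exported
# here as part of the statistics surface
from .experiment import ExperimentResult, run_experiment  # noqa: E402,F401
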