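"""End-to-end synthetic two-arm study driver.

Runs the full pipeline — panel generation, truth individuals, read
simulation, coverage summaries, leave-one-out imputation, confidence
filtering, NRC overall and by allele-frequency bin — for two (or more) arms
of samples whose read-simulation settings differ, then compares the arms
with Welch's t-tests on duplication rate, effective/nominal coverage ratio
and NRC.

Samples are paired across arms: sample *i* in every arm shares the same
truth individual and the same read-simulation random state, so arm
differences isolate the configuration difference (e.g. the duplicate rate)
rather than sampling noise.  The whole study is reproducible from one
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import concord as _concord
from .concord import DEFAULT_BIN_EDGES, nrc_by_af_bin
from .coverage import summarize_coverage
from .impute import HmmParams, filter_posteriors, impute_sample, likelihoods_from_pileups
from .synth import HaplotypePanel, ReadSimConfig, generate_panel, simulate_individual, simulate_pileup


def default_arm_configs(nominal_coverage: float = 1.0,
                        dup_low: float = 0.0027,
                        dup_high: float = 0.055) -> dict[str, ReadSimConfig]:
    """Two arms differing only in duplicate rate (low- vs high-duplication
    chemistry regimes)."""
    return {
        "low_dup": ReadSimConfig(nominal_coverage=nominal_coverage, dup_rate=dup_low),
        "high_dup": ReadSimConfig(nominal_coverage=nominal_coverage, dup_rate=dup_high),
    }


@dataclass(frozen=True)
class ExperimentResult:
    """Tables produced by :func:`run_experiment`."""

    per_sample: pd.DataFrame
    arm_summary: pd.DataFrame
    comparisons: dict
    nrc_by_bin: pd.DataFrame
    bin_edges: tuple
    seed: int

    def comparison_table(self) -> pd.DataFrame:
        return pd.concat(
            [c.summary().assign(metric=m) for m, c in self.comparisons.items()],
            ignore_index=True)

    def summary(self) -> str:
        lines = ["Per-arm summaries (mean over samples):",
                 self.arm_summary.to_string(index=False), "",
                 "Welch comparisons:",
                 self.comparison_table().to_string(index=False)]
        return "\n".join(lines)

    def save(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(out / "per_sample.tsv", sep="\t", index=False)
        self.arm_summary.to_csv(out / "arm_summary.tsv", sep="\t", index=False)
        self.comparison_table().to_csv(out / "comparisons.tsv", sep="\t", index=False)
        self.nrc_by_bin.to_csv(out / "nrc_by_bin.tsv", sep="\t", index=False)

    def plot(self, out_dir: str) -> list[str]:
        """Write duplication-rate / evenness histograms and the NRC-by-bin
        profile as PNGs; returns the written paths."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        arms = sorted(self.per_sample["arm"].unique())
        for col, fname, xlabel in [
                ("dup_rate", "dup_rate_hist.png", "duplication rate"),
                ("eff_to_nominal_ratio", "eff_ratio_hist.png",
                 "effective / nominal coverage ratio")]:
            fig, ax = plt.subplots(figsize=(5, 3.2))
            for arm in arms:
                vals = self.per_sample.loc[self.per_sample["arm"] == arm, col]
                ax.hist(vals, bins=12, alpha=0.6, label=arm)
            ax.set_xlabel(xlabel)
            ax.set_ylabel("samples")
            ax.legend()
            fig.tight_layout()
            path = out / fname
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for arm in arms:
            sub = self.nrc_by_bin[self.nrc_by_bin["arm"] == arm]
            mid = (sub["lo"] + sub["hi"]) / 2
            ax.plot(mid, sub["nrc_mean"], marker="o", label=arm)
        ax.set_xscale("log")
        ax.set_xlabel("minor allele frequency bin midpoint")
        ax.set_ylabel("mean NRC")
        ax.legend()
        fig.tight_layout()
        path = out / "nrc_by_af_bin.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
        return written


def run_experiment(n_samples_per_arm: int = 20,
                   arm_configs: Mapping[str, ReadSimConfig] | None = None, *,
                   panel: HaplotypePanel | None = None,
                   n_haplotypes: int = 40, n_sites: int = 2000,
                   ld_strength: float = 0.7, sfs_exponent: float = 1.0,
                   recomb_rate: float = 0.001, mutation_rate: float = 0.001,
                   hmm_params: HmmParams = HmmParams(),
                   bin_edges=DEFAULT_BIN_EDGES, min_base_quality: int = 13,
                   seed: int = 0, out_dir: str | None = None,
                   make_plots: bool = False) -> ExperimentResult:
    """Run the full synthetic study and return its tables.

    Per-sample seeds derive deterministically from ``seed``; the individual
    and the read-simulation stream are shared across arms for each sample
    index (paired design).
    """
    if n_samples_per_arm < 2:
        raise ValueError("need at least 2 samples per arm")
    if arm_configs is None:
        arm_configs = default_arm_configs()
    if panel is None:
        panel = generate_panel(n_haplotypes, n_sites, ld_strength=ld_strength,
                               sfs_exponent=sfs_exponent,
                               rng=np.random.default_rng([seed, 7]))
    af = panel.af

    rows = []
    bin_rows = []
    for i in range(n_samples_per_arm):
        individual = simulate_individual(
            panel, recomb_rate, mutation_rate,
            rng=np.random.default_rng([seed, 1, i]))
        for arm, cfg in arm_configs.items():
            try:
                pileups, tally = simulate_pileup(
                    individual, panel, cfg,
                    min_base_quality=min_base_quality,
                    rng=np.random.default_rng([seed, 2, i]))
                cov = summarize_coverage(pileups, tally,
                                         min_base_quality=min_base_quality)
                lik = likelihoods_from_pileups(pileups, cfg.base_error)
                post = impute_sample(lik, panel, individual.hap_indices,
                                     hmm_params)
                filt = filter_posteriors(post)
                rep = nrc_by_af_bin(filt.calls, individual.genotypes, af,
                                    bin_edges)
            except Exception as exc:  # annotate with sample context
                raise RuntimeError(
                    f"arm {arm!r}, sample {i}: {exc}") from exc
            rows.append({
                "arm": arm, "sample": i,
                "nominal_coverage": cov.nominal_coverage,
                "f_covered": cov.f_covered, "lambda_eff": cov.lambda_eff,
                "eff_to_nominal_ratio": cov.eff_to_nominal_ratio,
                "dup_rate": cov.dup_rate,
                "nrc": np.nan if rep.nrc is None else rep.nrc,
                "n_sites_compared": rep.n_intersect,
                "n_lowconf_filtered": filt.n_filtered,
            })
            for b in rep.per_bin:
                bin_rows.append({
                    "arm": arm, "sample": i, "lo": b.lo, "hi": b.hi,
                    "n_denom": b.n_denom, "n_match": b.n_match,
                    "nrc": np.nan if b.nrc is None else b.nrc,
                })

    per_sample = pd.DataFrame(rows)
    metrics = ["nominal_coverage", "f_covered", "lambda_eff",
               "eff_to_nominal_ratio", "dup_rate", "nrc",
               "n_lowconf_filtered"]
    arm_summary = (per_sample.groupby("arm")[metrics]
                   .agg(["mean", "std"]).reset_index())
    arm_summary.columns = ["arm"] + [f"{m}_{s}" for m, s in
                                     arm_summary.columns[1:]]

    from .stats import welch_t  # deferred: stats re-imports this module
    arms = list(arm_configs)
    comparisons = {}
    if len(arms) >= 2:
        a, b = arms[0], arms[1]
        for metric in ("dup_rate", "eff_to_nominal_ratio", "nrc"):
            va = per_sample.loc[per_sample["arm"] == a, metric].dropna()
            vb = per_sample.loc[per_sample["arm"] == b, metric].dropna()
            comparisons[metric] = welch_t(va, vb, labels=(a, b))

    bins = pd.DataFrame(bin_rows)
    grouped = bins.groupby(["arm", "lo", "hi"], sort=True)
    nrc_by_bin = grouped.agg(
        nrc_mean=("nrc", "mean"),            # mean over per-sample NRCs
        n_samples_defined=("nrc", "count"),
        n_denom_total=("n_denom", "sum"),
        n_match_total=("n_match", "sum"),
    ).reset_index()
    with np.errstate(invalid="ignore"):
        nrc_by_bin["nrc_pooled"] = (nrc_by_bin["n_match_total"]
                                    / nrc_by_bin["n_denom_total"].replace(0, np.nan))

    result = ExperimentResult(
        per_sample=per_sample, arm_summary=arm_summary,
        comparisons=comparisons, nrc_by_bin=nrc_by_bin,
        bin_edges=tuple(bin_edges), seed=seed)
    if out_dir is not None:
        result.save(out_dir)
        if make_plots:
            result.plot(out_dir)
    return result
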