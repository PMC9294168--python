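"""MR-PRESSO: pleiotropy residual sum and outlier machinery.

The procedure regresses the SNP→outcome effects on the SNP→exposure effects
(through the origin, inverse-variance weighted) and compares each SNP's
observed distance from the regression with the distance expected under the
null of no horizontal pleiotropy, via Monte-Carlo simulation:

* global test — the weighted residual sum of squares (RSS), with each SNP's
  residual taken against the leave-one-out slope, against its simulated
  null distribution;
* outlier test — per-SNP empirical p-values on squared residuals, flagged
  at a Bonferroni-adjusted threshold;
* distortion test — whether removing the flagged SNPs shifts the causal
  estimate more than random subsetting would.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .estimators import MrEstimate, ivw, ratio_estimates
from .gwas_data import HarmonizedInstrument

__all__ = ["PressoConfig", "PressoReport", "presso_global", "presso_outlier",
           "presso_distortion", "run_presso"]


@dataclass(frozen=True)
class PressoConfig:
    """Monte-Carlo settings for the MR-PRESSO tests.

    ``outlier_significance`` is the per-SNP level, Bonferroni-divided by the
    number of instruments unless ``bonferroni=False``.  The smallest
    attainable p is 1/(n_sim+1), so resolving very small global p-values
    needs n_sim well above the default 1000 (e.g. >= 10,000 for p ~ 1e-4).
    """

    n_sim: int = 1000
    outlier_significance: float = 0.05
    bonferroni: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")


@dataclass
class GlobalTestResult:
    """Observed RSS, its empirical p, and the simulated residual draws."""

    rss_obs: float
    global_pval: float
    resid_obs: np.ndarray          # observed per-SNP residuals r_j
    sim_resid_sq: np.ndarray       # (n_sim, k) simulated squared residuals
    weights: np.ndarray            # 1/sigma_y^2


@dataclass
class PressoReport:
    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int
    outlier_rsids: list[str]
    distortion_pval: float | None
    corrected: MrEstimate | None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outliers": self.outlier_rsids,
            "distortion_pval": self.distortion_pval,
            "corrected": None
            if self.corrected is None
            else {
                "method": self.corrected.method,
                "beta": self.corrected.beta,
                "se": self.corrected.se,
                "or": self.corrected.odds_ratio,
                "ci_low": self.corrected.ci_low,
                "ci_high": self.corrected.ci_high,
                "pval": self.corrected.pval,
                "n_snp": self.corrected.n_snp,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes of the through-origin weighted regression.

    With weights w = 1/sigma_y^2 the full-sample slope is
    (Σ w g Γ)/(Σ w g²); element j of the result excludes SNP j.  Works on
    1-D arrays and row-wise on 2-D (replicate × SNP) arrays.
    """
    num = w * g * G
    den = w * g * g
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def presso_global(
    insts: Sequence[HarmonizedInstrument], cfg: PressoConfig
) -> GlobalTestResult | None:
    """Global heterogeneity test on the weighted residual sum of squares.

    Observed residual for SNP j is r_j = Γ_j − β̂_(−j) γ_j against the
    leave-one-out slope; RSS = Σ w_j r_j² with w_j = 1/σ_Yj².  The null
    distribution redraws γ*_j ~ N(γ_j, σ_Xj²), Γ*_j ~ N(β̂_(−j) γ_j, σ_Yj²)
    and recomputes the RSS identically; the empirical p carries an add-one
    correction so it is never zero.  Returns ``None`` below 4 instruments.
    """
    if len(insts) < 4:
        return None
    g = np.array([i.gamma for i in insts])
    G = np.array([i.Gamma for i in insts])
    sx = np.array([i.sigma_x for i in insts])
    sy = np.array([i.sigma_y for i in insts])
    w = 1 / sy ** 2

    beta_loo = _loo_slopes(g, G, w)
    resid_obs = G - beta_loo * g
    rss_obs = float(np.sum(w * resid_obs ** 2))

    rng = np.random.default_rng(cfg.seed)
    g_star = rng.normal(loc=g, scale=sx, size=(cfg.n_sim, len(insts)))
    G_star = rng.normal(loc=beta_loo * g, scale=sy, size=(cfg.n_sim, len(insts)))
    beta_loo_star = _loo_slopes(g_star, G_star, np.broadcast_to(w, g_star.shape))
    resid_star = G_star - beta_loo_star * g_star
    rss_sim = np.sum(w * resid_star ** 2, axis=1)

    pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (cfg.n_sim + 1)
    return GlobalTestResult(
        rss_obs=rss_obs,
        global_pval=pval,
        resid_obs=resid_obs,
        sim_resid_sq=resid_star ** 2,
        weights=w,
    )


def presso_outlier(
    insts: Sequence[HarmonizedInstrument],
    global_result: GlobalTestResult,
    cfg: PressoConfig,
) -> list[str]:
    """Per-SNP outlier test on the residual distributions of the global test.

    Empirical p_j = (1 + #{r*_j² ≥ r_j²})/(n_sim + 1); SNP j is flagged when
    p_j falls below ``outlier_significance`` (divided by k under the default
    Bonferroni adjustment).
    """
    k = len(insts)
    obs_sq = global_result.resid_obs ** 2
    exceed = np.sum(global_result.sim_resid_sq >= obs_sq[None, :], axis=0)
    pvals = (1 + exceed) / (cfg.n_sim + 1)
    threshold = cfg.outlier_significance / k if cfg.bonferroni else cfg.outlier_significance
    return [insts[j].rsid for j in range(k) if pvals[j] < threshold]


def presso_distortion(
    insts: Sequence[HarmonizedInstrument],
    outlier_rsids: Sequence[str],
    cfg: PressoConfig,
) -> tuple[float, MrEstimate]:
    """Distortion test: does removing the outliers shift the IVW estimate?

    The corrected estimate is the fixed-effect IVW on the retained SNPs.
    The distortion statistic D = (β̂_raw − β̂_corrected)/β̂_corrected is
    referred to its bootstrap null built from random subsets of the same
    size as the retained set; the empirical p is two-sided on |D|.
    """
    if not outlier_rsids:
        raise ValueError("distortion test requires at least one flagged outlier")
    flagged = set(outlier_rsids)
    retained = [i for i in insts if i.rsid not in flagged]
    if not retained:
        raise ValueError("all instruments flagged as outliers; nothing retained")

    raw, _ = ivw(ratio_estimates(insts), model_rule="fixed")
    corrected, _ = ivw(ratio_estimates(retained), model_rule="fixed")
    d_obs = (raw.beta - corrected.beta) / corrected.beta

    rng = np.random.default_rng(cfg.seed + 1)
    k, m = len(insts), len(retained)
    count = 0
    for _ in range(cfg.n_sim):
        idx = rng.choice(k, size=m, replace=False)
        sub, _ = ivw(ratio_estimates([insts[j] for j in idx]), model_rule="fixed")
        d_b = (raw.beta - sub.beta) / sub.beta
        if abs(d_b) >= abs(d_obs):
            count += 1
    pval = (1 + count) / (cfg.n_sim + 1)
    return pval, corrected


def run_presso(
    insts: Sequence[HarmonizedInstrument], cfg: PressoConfig | None = None
) -> PressoReport | None:
    """Run global, outlier, and (when outliers are flagged) distortion tests.

    With no flagged outliers the distortion stage is not invoked and
    ``corrected`` is ``None``; the reporting layer then uses the raw IVW
    estimate unchanged.  Returns ``None`` below 4 instruments.
    """
    cfg = cfg or PressoConfig()
    global_result = presso_global(insts, cfg)
    if global_result is None:
        return None
    outliers = presso_outlier(insts, global_result, cfg)
    distortion_pval: float | None = None
    corrected: MrEstimate | None = None
    if outliers and len(outliers) < len(insts):
        distortion_pval, corrected = presso_distortion(insts, outliers, cfg)
    return PressoReport(
        rss_obs=global_result.rss_obs,
        global_pval=global_result.global_pval,
        n_sim=cfg.n_sim,
        seed=cfg.seed,
        outlier_rsids=outliers,
        distortion_pval=distortion_pval,
        corrected=corrected,
    )
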