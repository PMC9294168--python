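"""Causal-effect estimators for summary-level Mendelian randomization.

Each instrument j contributes a Wald ratio θ_j = Γ_j/γ_j (log-odds of the
outcome per 1 SD of exposure).  The estimators combine these ratios under
different robustness assumptions:

* inverse-variance weighted (IVW) mean — the primary estimator, with a
  Cochran's-Q–driven fixed/random-effects model choice;
* weighted median — consistent when instruments carrying ≥ 50% of the
  weight are valid;
* maximum likelihood — joint Gaussian likelihood of both samples' effects
  under a linear exposure–outcome relation;
* MR-Egger regression — weighted regression of Γ on γ with a free
  intercept, whose intercept estimates directional pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .gwas_data import HarmonizedInstrument

__all__ = [
    "Z_95",
    "RatioEstimate",
    "MrEstimate",
    "QStatistic",
    "EggerResult",
    "ConvergenceError",
    "wald_ratio",
    "ratio_estimates",
    "cochran_q",
    "ivw",
    "weighted_median",
    "max_likelihood",
    "egger",
]

#: Normal 97.5th percentile used for all 95% intervals (matches standard
#: reporting arithmetic to 5 decimals).
Z_95 = 1.95996


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries scipy diagnostics."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its inverse-variance weight."""

    rsid: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if self.se_theta <= 0:
            raise ValueError(f"{self.rsid}: se_theta must be > 0")

    @property
    def weight(self) -> float:
        return self.se_theta ** -2


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate: log-odds per 1 SD of exposure.

    ``ci_low``/``ci_high`` are the 95% bounds on the odds-ratio scale.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int) -> "MrEstimate":
        z = beta / se
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=math.exp(beta - Z_95 * se),
            ci_high=math.exp(beta + Z_95 * se),
            pval=float(2 * stats.norm.sf(abs(z))),
            n_snp=n_snp,
        )


@dataclass(frozen=True)
class QStatistic:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression: intercept (pleiotropy) and slope (causal) terms."""

    intercept: float
    se_intercept: float
    p_intercept: float
    slope: float
    se_slope: float
    p_slope: float
    n_snp: int

    def slope_estimate(self) -> MrEstimate:
        est = MrEstimate.from_beta_se("egger_slope", self.slope, self.se_slope, self.n_snp)
        # keep the t-based p from the regression rather than the normal one
        return MrEstimate(
            method=est.method, beta=est.beta, se=est.se,
            ci_low=est.ci_low, ci_high=est.ci_high,
            pval=self.p_slope, n_snp=est.n_snp,
        )


# ---------------------------------------------------------------------------
# Wald ratios and heterogeneity
# ---------------------------------------------------------------------------

def wald_ratio(inst: HarmonizedInstrument, se_order: str = "first") -> RatioEstimate:
    """Per-SNP causal estimate θ = Γ/γ.

    ``se_order="first"`` uses the delta-method leading term σ_Y/|γ|;
    ``"second"`` adds the exposure-uncertainty term
    sqrt(σ_Y²/γ² + Γ²σ_X²/γ⁴).
    """
    if inst.gamma == 0:
        raise ZeroDivisionError(f"{inst.rsid}: undefined Wald ratio (gamma = 0)")
    theta = inst.Gamma / inst.gamma
    if se_order == "first":
        se = inst.sigma_y / abs(inst.gamma)
    elif se_order == "second":
        se = math.sqrt(
            inst.sigma_y ** 2 / inst.gamma ** 2
            + inst.Gamma ** 2 * inst.sigma_x ** 2 / inst.gamma ** 4
        )
    else:
        raise ValueError(f"unknown se_order {se_order!r}")
    return RatioEstimate(rsid=inst.rsid, theta=theta, se_theta=se)


def ratio_estimates(
    insts: Sequence[HarmonizedInstrument], se_order: str = "first"
) -> list[RatioEstimate]:
    return [wald_ratio(i, se_order) for i in insts]


def cochran_q(ratios: Sequence[RatioEstimate], beta_hat: float) -> QStatistic | None:
    """Weighted heterogeneity statistic Q = Σ w_j (θ_j − β̂)², df = k−1.

    Returns ``None`` (not applicable) for fewer than two ratios.
    """
    if len(ratios) < 2:
        return None
    w = np.array([r.weight for r in ratios])
    th = np.array([r.theta for r in ratios])
    q = float(np.sum(w * (th - beta_hat) ** 2))
    df = len(ratios) - 1
    return QStatistic(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(
    ratios: Sequence[RatioEstimate],
    model_rule: str = "auto",
    het_alpha: float = 0.05,
) -> tuple[MrEstimate, QStatistic | None]:
    """Inverse-variance-weighted mean of the Wald ratios.

    The fixed-effect SE is (Σw)^{-1/2}; the multiplicative random-effects
    model scales it by max(1, sqrt(Q/(k−1))), leaving the point estimate
    unchanged.  ``model_rule`` is "fixed", "random", or "auto" (default):
    random effects when the Q test rejects at ``het_alpha``.
    """
    if not ratios:
        raise ValueError("ivw requires at least one ratio")
    if model_rule not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown model_rule {model_rule!r}")
    w = np.array([r.weight for r in ratios])
    th = np.array([r.theta for r in ratios])
    beta = float(np.sum(w * th) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = cochran_q(ratios, beta)

    use_random = model_rule == "random" or (
        model_rule == "auto" and q is not None and q.pval < het_alpha
    )
    if use_random and q is not None and q.df > 0:
        se = se_fixed * max(1.0, math.sqrt(q.q / q.df))
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_random" if use_random else "ivw_fixed"
    return MrEstimate.from_beta_se(method, beta, se, len(ratios)), q


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    ww = w[order]
    s = np.cumsum(ww)
    p = (s - ww / 2) / s[-1]
    return float(np.interp(0.5, p, th))


def weighted_median(
    ratios: Sequence[RatioEstimate],
    n_boot: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> MrEstimate:
    """Weighted median of the Wald ratios with a parametric-bootstrap SE.

    The point estimate interpolates θ against the standardized cumulative
    weight p_j = (S_j − w_j/2)/S_k at p = 0.5.  The SE is the standard
    deviation of the estimator over ``n_boot`` replicates drawing
    θ*_j ~ Normal(θ_j, se_j²).  ``weighted=False`` gives the simple
    (equal-weight) median variant.
    """
    if len(ratios) < 2:
        raise ValueError("weighted median requires at least 2 ratios")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    th = np.array([r.theta for r in ratios])
    se = np.array([r.se_theta for r in ratios])
    w = np.array([r.weight for r in ratios]) if weighted else np.ones(len(ratios))
    point = _weighted_median_point(th, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=th, scale=se, size=(n_boot, len(ratios)))
    boot = np.array([_weighted_median_point(row, w) for row in draws])
    se_boot = float(np.std(boot, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    return MrEstimate.from_beta_se(method, point, se_boot, len(ratios))


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

def max_likelihood(insts: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """Likelihood-based estimate under a linear exposure–outcome relation.

    Maximizes over (β, γ_1..γ_k) the joint Gaussian log-likelihood
    Σ_j [ logN(γ̂_j; γ_j, σ_Xj²) + logN(Γ̂_j; β γ_j, σ_Yj²) ], the two
    samples being independent.  The nuisance γ_j have a closed-form optimum
    for fixed β, so β is found by minimizing the profile objective
    (tolerance 1e-10), started at the IVW estimate; the SE of β comes from
    the observed information (block inverse of the full Hessian).
    """
    if not insts:
        raise ValueError("max_likelihood requires at least one instrument")
    g = np.array([i.gamma for i in insts])
    sx2 = np.array([i.sigma_x for i in insts]) ** 2
    G = np.array([i.Gamma for i in insts])
    sy2 = np.array([i.sigma_y for i in insts]) ** 2

    def prof_gamma(beta: float) -> np.ndarray:
        return (g / sx2 + beta * G / sy2) / (1 / sx2 + beta ** 2 / sy2)

    def nll(beta: float) -> float:
        gam = prof_gamma(beta)
        return float(
            np.sum((g - gam) ** 2 / (2 * sx2) + (G - beta * gam) ** 2 / (2 * sy2))
        )

    b0, _ = ivw(ratio_estimates(insts), model_rule="fixed")
    res = optimize.minimize(
        lambda x: nll(x[0]),
        x0=[b0.beta],
        method="Nelder-Mead",
        options={"fatol": 1e-10, "xatol": 1e-12, "maxiter": 10_000},
    )
    if not res.success:
        raise ConvergenceError(f"likelihood optimization failed: {res.message}")
    beta = float(res.x[0])

    gam = prof_gamma(beta)
    h_bb = float(np.sum(gam ** 2 / sy2))
    h_bg = (2 * beta * gam - G) / sy2
    h_gg = 1 / sx2 + beta ** 2 / sy2
    info = h_bb - float(np.sum(h_bg ** 2 / h_gg))
    if info <= 0:
        raise ConvergenceError("observed information for beta is not positive")
    se = info ** -0.5
    return MrEstimate.from_beta_se("max_likelihood", beta, se, len(insts))


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(insts: Sequence[HarmonizedInstrument]) -> EggerResult | None:
    """MR-Egger: weighted regression of Γ_j on γ_j with a free intercept.

    Instruments are first oriented so every γ_j > 0 (negating both effects
    where needed — required for the estimator's validity).  Weights are
    1/σ_Yj²; inference is t-based with k−2 df.  Returns ``None`` (not
    applicable) for fewer than 3 instruments.
    """
    if len(insts) < 3:
        return None
    g = np.array([i.gamma for i in insts])
    G = np.array([i.Gamma for i in insts])
    sy2 = np.array([i.sigma_y for i in insts]) ** 2
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip

    model = sm.WLS(G, sm.add_constant(g), weights=1 / sy2).fit()
    return EggerResult(
        intercept=float(model.params[0]),
        se_intercept=float(model.bse[0]),
        p_intercept=float(model.pvalues[0]),
        slope=float(model.params[1]),
        se_slope=float(model.bse[1]),
        p_slope=float(model.pvalues[1]),
        n_snp=len(insts),
    )
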