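"""Orchestration of the full MR battery over an exposure × outcome grid.

For every pair the battery runs: instrument selection → LD pruning →
harmonization → instrument-strength screening → Wald ratios → Cochran's Q →
IVW (fixed/random chosen by the Q test) → weighted median → maximum
likelihood → MR-Egger → MR-PRESSO → leave-one-out.  Methods whose
preconditions are unmet (e.g. Egger below 3 SNPs) are recorded as
not-applicable, never silently omitted.  Grid-level inference applies a
Bonferroni threshold of 0.05/(n_exposures × n_outcomes); p-values between
that threshold and 0.05 count as suggestive evidence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import gwas_data, sensitivity
from .estimators import (EggerResult, MrEstimate, QStatistic, egger, ivw,
                         max_likelihood, ratio_estimates, weighted_median)
from .gwas_data import (HarmonizedInstrument, LdTable, SnpAssociation,
                        harmonize_pairs, instrument_strength, ld_prune,
                        select_instruments)
from .presso import PressoConfig, PressoReport, run_presso

logger = logging.getLogger("cytomr")

__all__ = ["AnalysisConfig", "PairResult", "GridReport", "classify",
           "run_pair", "run_grid", "pair_seed", "estimates_to_tsv"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and settings of the battery (YAML-serializable)."""

    p_instrument: float = 5e-8
    r2_prune: float = 0.1
    palindrome_policy: str = "freq"
    palindrome_ambiguity: float = 0.42
    wald_se_order: str = "first"
    het_alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    alpha_suggestive: float = 0.05
    f_formula: str = "unadjusted"
    min_f: float = 10.0   # instruments below this log a weak-instrument warning

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        presso = raw.pop("presso", None)
        if isinstance(presso, dict) and "n_sim" in presso:
            raw["presso_n_sim"] = presso["n_sim"]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PairResult:
    """All battery outputs for one exposure–outcome pair."""

    exposure: str
    outcome: str
    k: int
    classification: str                     # significant | suggestive | null | not_testable
    reason: str | None = None
    f_stat: float | None = None
    r2_total: float | None = None
    estimates: dict[str, MrEstimate | None] = field(default_factory=dict)
    q: QStatistic | None = None
    egger_result: EggerResult | None = None
    presso_report: PressoReport | None = None
    loo_max_abs_dev: float | None = None
    dropped: list = field(default_factory=list)

    @property
    def primary(self) -> MrEstimate | None:
        return self.estimates.get("ivw")


@dataclass
class GridReport:
    """Battery results for every pair, with the Bonferroni verdict."""

    results: list[PairResult]
    alpha_bonferroni: float
    counts: dict[str, int]

    def to_matrix(self, value: str = "or") -> pd.DataFrame:
        """Numeric twin of the published heatmap: OR (or classification) matrix."""
        exposures = sorted({r.exposure for r in self.results})
        outcomes = sorted({r.outcome for r in self.results})
        mat = pd.DataFrame(index=exposures, columns=outcomes, dtype=object)
        for r in self.results:
            if value == "or":
                mat.loc[r.exposure, r.outcome] = (
                    r.primary.odds_ratio if r.primary else float("nan"))
            else:
                mat.loc[r.exposure, r.outcome] = r.classification
        return mat

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alpha_bonferroni": self.alpha_bonferroni,
            "counts": self.counts,
            "pairs": [_pair_payload(r) for r in self.results],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def classify(pval: float, alpha_bonf: float, alpha_suggestive: float = 0.05) -> str:
    """Grid-level verdict: strict p < alpha_bonf is significant; the
    suggestive band is the half-open interval [alpha_bonf, alpha_suggestive),
    empty for an uncorrected 1×1 grid where the two thresholds coincide."""
    if not (0 < alpha_bonf <= alpha_suggestive < 1):
        raise ValueError("need 0 < alpha_bonf <= alpha_suggestive < 1")
    if pval < alpha_bonf:
        return "significant"
    if pval < alpha_suggestive:
        return "suggestive"
    return "null"


def pair_seed(master_seed: int, exposure: str, outcome: str) -> int:
    """Deterministic per-pair seed, independent of grid traversal order."""
    digest = hashlib.sha256(f"{exposure}|{outcome}".encode()).digest()
    return (master_seed ^ int.from_bytes(digest[:4], "little")) % (2**31)


def run_pair(
    exposure_assocs: Sequence[SnpAssociation],
    outcome_assocs: Sequence[SnpAssociation],
    exposure: str,
    outcome: str,
    config: AnalysisConfig | None = None,
    ld: LdTable | None = None,
    exclusions: Mapping[str, str] | None = None,
    alpha_bonf: float | None = None,
    seed: int = 0,
) -> PairResult:
    """Run the full battery on one exposure–outcome pair.

    ``alpha_bonf`` defaults to ``config.alpha_suggestive`` (a 1×1 grid);
    :func:`run_grid` passes the grid-wide corrected threshold.  ``seed``
    drives the weighted-median bootstrap and the PRESSO Monte Carlo.
    """
    cfg = config or AnalysisConfig()
    if alpha_bonf is None:
        alpha_bonf = cfg.alpha_suggestive  # lone pair: no correction

    def not_testable(reason: str, dropped=()) -> PairResult:
        logger.info("%s vs %s: not testable (%s)", exposure, outcome, reason)
        return PairResult(exposure=exposure, outcome=outcome, k=0,
                          classification="not_testable", reason=reason,
                          dropped=list(dropped))

    selected = select_instruments(exposure_assocs, cfg.p_instrument)
    if not selected:
        return not_testable("no genome-wide-significant instruments")
    pruned = ld_prune(selected, ld, cfg.r2_prune)
    insts, drops = harmonize_pairs(
        pruned, outcome_assocs, cfg.palindrome_policy, cfg.palindrome_ambiguity)
    if exclusions:
        kept = [i for i in insts if i.rsid not in exclusions]
        drops += [gwas_data.DropVerdict(i.rsid, f"excluded: {exclusions[i.rsid]}")
                  for i in insts if i.rsid in exclusions]
        insts = kept
    if not insts:
        return not_testable("no harmonizable instruments", drops)

    k = len(insts)
    n_exp = next((a.n for a in exposure_assocs if a.n), None)
    f_stat = r2_total = None
    if n_exp and n_exp > k + 1:
        try:
            r2_total, f_stat = instrument_strength(
                [i.gamma for i in insts], [i.sigma_x for i in insts],
                [i.eaf for i in insts], n_exp, cfg.f_formula)
            if f_stat < cfg.min_f:
                logger.warning("%s vs %s: weak instruments (F = %.1f < %.0f)",
                               exposure, outcome, f_stat, cfg.min_f)
        except ValueError as exc:
            logger.warning("%s vs %s: F-statistic unavailable (%s)",
                           exposure, outcome, exc)

    ratios = ratio_estimates(insts, cfg.wald_se_order)
    ivw_est, q = ivw(ratios, model_rule="auto", het_alpha=cfg.het_alpha)

    estimates: dict[str, MrEstimate | None] = {"ivw": ivw_est}
    estimates["weighted_median"] = (
        weighted_median(ratios, cfg.n_boot, seed) if k >= 3 else None)
    estimates["max_likelihood"] = max_likelihood(insts)
    egger_result = egger(insts)
    estimates["egger_slope"] = egger_result.slope_estimate() if egger_result else None

    presso_report = run_presso(
        insts, PressoConfig(n_sim=cfg.presso_n_sim, seed=seed))

    loo_max = None
    if k >= 2:
        records = sensitivity.leave_one_out(
            insts, "auto", cfg.het_alpha, cfg.wald_se_order)
        loo_max = max(abs(r.estimate.beta - ivw_est.beta) for r in records)

    cls = classify(ivw_est.pval, alpha_bonf, cfg.alpha_suggestive)
    return PairResult(
        exposure=exposure, outcome=outcome, k=k, classification=cls,
        f_stat=f_stat, r2_total=r2_total, estimates=estimates, q=q,
        egger_result=egger_result, presso_report=presso_report,
        loo_max_abs_dev=loo_max, dropped=drops,
    )


def run_grid(
    exposures: Mapping[str, Sequence[SnpAssociation]],
    outcomes: Mapping[str, Sequence[SnpAssociation]],
    config: AnalysisConfig | None = None,
    ld: LdTable | None = None,
    exclusions: Mapping[str, str] | None = None,
    master_seed: int = 0,
    drop_shared: bool = True,
) -> GridReport:
    """Run the battery over every exposure × outcome pair.

    Instruments shared between exposures are removed up front (as in a
    multi-cytokine screen); the Bonferroni threshold is recomputed from the
    actual grid dimensions.  Per-pair failures are captured as
    ``not_testable`` results rather than aborting the grid; stochastic
    stages use per-pair seeds derived from ``master_seed`` and the pair's
    names, so results are independent of traversal order.
    """
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    cfg = config or AnalysisConfig()
    alpha_bonf = cfg.alpha_suggestive / (len(exposures) * len(outcomes))

    exp_map = dict(exposures)
    if drop_shared and len(exp_map) > 1:
        selected = {name: select_instruments(assocs, cfg.p_instrument)
                    for name, assocs in exp_map.items()}
        _, shared = gwas_data.exclude_shared_snps(selected)
        if shared:
            exp_map = {name: [a for a in assocs if a.rsid not in shared]
                       for name, assocs in exp_map.items()}

    results: list[PairResult] = []
    for exp_name, exp_assocs in exp_map.items():
        for out_name, out_assocs in outcomes.items():
            seed = pair_seed(master_seed, exp_name, out_name)
            try:
                res = run_pair(exp_assocs, out_assocs, exp_name, out_name,
                               cfg, ld, exclusions, alpha_bonf, seed)
            except Exception as exc:  # surface, don't abort the grid
                logger.error("%s vs %s failed: %s", exp_name, out_name, exc)
                res = PairResult(exposure=exp_name, outcome=out_name, k=0,
                                 classification="not_testable",
                                 reason=f"error: {exc}")
            results.append(res)

    counts: dict[str, int] = {}
    for r in results:
        counts[r.classification] = counts.get(r.classification, 0) + 1
    return GridReport(results=results, alpha_bonferroni=alpha_bonf, counts=counts)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def estimates_to_tsv(results: Sequence[PairResult], path: str | Path) -> None:
    """Long-format TSV of every method's estimate for every pair."""
    rows = []
    for r in results:
        for method, est in r.estimates.items():
            row = {"exposure": r.exposure, "outcome": r.outcome, "method": method}
            if est is None:
                row.update({"n_snp": r.k, "beta": None, "se": None, "or": None,
                            "ci_low": None, "ci_high": None, "pval": None,
                            "q": None, "q_pval": None, "model": "not_applicable"})
            else:
                row.update({
                    "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
                    "or": est.odds_ratio, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "pval": est.pval,
                    "q": r.q.q if r.q else None,
                    "q_pval": r.q.pval if r.q else None,
                    "model": est.method,
                })
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _pair_payload(r: PairResult) -> dict:
    def est(e: MrEstimate | None):
        if e is None:
            return None
        return {"method": e.method, "beta": e.beta, "se": e.se,
                "or": e.odds_ratio, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "pval": e.pval, "n_snp": e.n_snp}

    return {
        "exposure": r.exposure,
        "outcome": r.outcome,
        "k": r.k,
        "classification": r.classification,
        "reason": r.reason,
        "f_stat": r.f_stat,
        "r2_total": r.r2_total,
        "estimates": {m: est(e) for m, e in r.estimates.items()},
        "q": None if r.q is None else {"q": r.q.q, "df": r.q.df, "pval": r.q.pval},
        "egger": None if r.egger_result is None else {
            "intercept": r.egger_result.intercept,
            "se_intercept": r.egger_result.se_intercept,
            "p_intercept": r.egger_result.p_intercept,
            "slope": r.egger_result.slope,
            "se_slope": r.egger_result.se_slope,
            "p_slope": r.egger_result.p_slope,
        },
        "presso": None if r.presso_report is None else json.loads(
            r.presso_report.to_json()),
        "loo_max_abs_dev": r.loo_max_abs_dev,
        "dropped": [
            {"rsid": d.rsid, "reason": d.reason} for d in r.dropped
        ],
    }
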