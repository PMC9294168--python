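"""Synthetic two-sample GWAS summary statistics and published-table fixtures.

The generator draws per-SNP true exposure effects γ_j, adds horizontal
pleiotropy α_j under a configurable mode, sets the true outcome effect to
Γ_j = β·γ_j + α_j, and emits noisy observed summaries for two independent
samples — exactly the structure the downstream estimators assume, with
every latent quantity retained in a truth record.

The fixture pairs reconstruct the per-SNP odds ratios and 95% confidence
intervals printed for the two headline cytokine–cancer associations
(IL-18 → acute myeloid leukemia, 16 SNPs; IL-17 → stomach cancer, 2 SNPs)
back onto the log-odds scale: θ = ln OR, se = (ln CI_hi − ln CI_lo)/(2·1.95996).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import Z_95, RatioEstimate
from .gwas_data import HarmonizedInstrument, LdTable, SnpAssociation

logger = logging.getLogger("cytomr")

__all__ = ["SimulationConfig", "FixturePair", "simulate_pair",
           "make_fixture_pairs", "simulate_grid"]

# Non-palindromic allele pairs used for simulated SNPs, so that default
# harmonization keeps every variant.
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one simulated exposure–outcome pair.

    Defaults mirror the study's data scale: a cytokine GWAS of 8,293
    individuals (exposure in SD units) against a biobank cancer GWAS of
    456,348 participants with a small case fraction.  ``gamma_mean``/
    ``gamma_sd`` give instrument strengths that clear genome-wide
    significance at that exposure sample size.
    """

    k: int = 30
    beta_true: float = 0.0
    gamma_mean: float = 0.15
    gamma_sd: float = 0.05
    n_exposure: int = 8293
    n_outcome: int = 456_348
    case_fraction: float = 0.02
    pleiotropy_mode: str = "none"      # none | balanced | directional
    tau: float = 0.0                   # pleiotropy SD
    mu_alpha: float = 0.0              # directional pleiotropy mean
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    ld_blocks: tuple[tuple[int, float], ...] = ()   # (block size, within-block r2)
    n_shared: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0 <= self.outlier_frac < 1):
            raise ValueError("outlier_frac must be in [0,1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")


def _sigma_x(eaf: np.ndarray, n: int) -> np.ndarray:
    # SE of a per-allele effect on a unit-variance trait
    return 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n)


def _sigma_y(eaf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    # log-odds SE via the effective-sample-size approximation
    return 1.0 / np.sqrt(n * case_fraction * 2 * eaf * (1 - eaf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)


def simulate_pair(
    cfg: SimulationConfig,
    rsid_prefix: str = "rs",
    rsid_start: int = 1,
) -> tuple[list[SnpAssociation], list[SnpAssociation], LdTable, dict]:
    """Simulate one exposure GWAS + outcome GWAS over the same k SNPs.

    True model: Γ_j = β γ_j + α_j with α_j = 0 ("none"),
    ~N(0, τ²) ("balanced"), or ~N(μ_α, τ²) ("directional"); a fraction
    ``outlier_frac`` of SNPs (at least one when the fraction is positive)
    has its pleiotropic effect multiplied by ``outlier_scale``.  Observed
    effects add sampling noise at SEs set by allele frequency and sample
    size.  Returns the two association lists, an LD table realizing
    ``ld_blocks``, and a truth record of every latent quantity.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    eaf = rng.uniform(0.05, 0.5, size=k)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=k)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(k)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.tau, size=k)
    else:
        alpha = rng.normal(cfg.mu_alpha, cfg.tau, size=k)

    outlier_idx: list[int] = []
    if cfg.outlier_frac > 0:
        n_out = max(1, int(round(cfg.outlier_frac * k)))
        outlier_idx = sorted(rng.choice(k, size=n_out, replace=False).tolist())
        base = alpha[outlier_idx]
        # give silent (alpha=0) modes a unit pleiotropic effect to scale
        base = np.where(base == 0, 1.0, base)
        alpha[outlier_idx] = base * cfg.outlier_scale
    Gamma_true = cfg.beta_true * gamma + alpha

    sx = _sigma_x(eaf, cfg.n_exposure)
    sy = _sigma_y(eaf, cfg.n_outcome, cfg.case_fraction)
    gamma_hat = rng.normal(gamma, sx)
    Gamma_hat = rng.normal(Gamma_true, sy)

    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    chroms = rng.integers(1, 23, size=k)
    positions = rng.integers(1, 2_000_000_00, size=k)

    exposure, outcome = [], []
    exp_p = _pvals(gamma_hat, sx)
    out_p = _pvals(Gamma_hat, sy)
    for j in range(k):
        ea, oa = _ALLELE_PAIRS[allele_idx[j]]
        common = dict(
            rsid=f"{rsid_prefix}{rsid_start + j}",
            chrom=str(chroms[j]),
            pos=int(positions[j]),
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf[j]),
        )
        exposure.append(SnpAssociation(
            beta=float(gamma_hat[j]), se=float(sx[j]), pval=float(exp_p[j]),
            n=cfg.n_exposure, **common))
        outcome.append(SnpAssociation(
            beta=float(Gamma_hat[j]), se=float(sy[j]), pval=float(out_p[j]),
            n=cfg.n_outcome, **common))

    ld = LdTable()
    pos = 0
    for size, r2 in cfg.ld_blocks:
        block = [exposure[j].rsid for j in range(pos, min(pos + size, k))]
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                ld.set(block[a], block[b], r2)
        pos += size
        if pos >= k:
            break

    truth = {
        "beta_true": cfg.beta_true,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "Gamma_true": Gamma_true.tolist(),
        "sigma_x": sx.tolist(),
        "sigma_y": sy.tolist(),
        "eaf": eaf.tolist(),
        "outlier_indices": outlier_idx,
        "seed": cfg.seed,
    }
    return exposure, outcome, ld, truth


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

# Per-SNP rows (rsid, chrom, pos, effect allele, OR, CI low, CI high) of the
# two headline associations.  The rs7601267 row is printed with P = 0.029,
# which is internally inconsistent with its CI spanning 1; the fixture keeps
# the OR and CI and ignores that printed p.
_IL18_AML_ROWS = [
    ("rs61902693", "2", 31850035, "G", 0.82, 0.26, 2.60),
    ("rs144736172", "2", 31968142, "T", 0.49, 0.22, 1.09),
    ("rs71478720", "2", 32226986, "G", 0.76, 0.39, 1.49),
    ("rs71446036", "2", 32272399, "G", 0.37, 0.16, 0.87),
    ("rs6716179", "2", 32393076, "C", 0.51, 0.21, 1.26),
    ("rs212761", "2", 32429288, "C", 0.38, 0.17, 0.85),
    ("rs141091241", "2", 32466607, "G", 1.03, 0.33, 3.21),
    ("rs212724", "2", 32467489, "C", 0.44, 0.20, 0.93),
    ("rs385076", "2", 32489851, "C", 0.40, 0.20, 0.79),
    ("rs17229943", "2", 32659489, "G", 1.21, 0.39, 3.79),
    ("rs116656892", "5", 68186028, "C", 1.92, 0.73, 5.03),
    ("rs7601267", "5", 68535015, "C", 1.06, 0.33, 3.56),
    ("rs115267715", "5", 68682536, "C", 0.25, 0.04, 1.62),
    ("rs660558", "11", 112009605, "C", 0.27, 0.08, 0.89),
    ("rs2038534", "11", 112111460, "C", 0.94, 0.29, 3.10),
    ("rs212722", "11", 112250980, "C", 0.44, 0.20, 0.93),
]

_IL17_STOMACH_ROWS = [
    ("rs2305051", "3", 122843212, "C", 0.14, 0.04, 0.49),
    ("rs1530455", "3", 122854899, "C", 0.17, 0.05, 0.52),
]


@dataclass(frozen=True)
class FixtureSnp:
    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    odds_ratio: float
    ci_low: float
    ci_high: float

    @property
    def theta(self) -> float:
        return float(np.log(self.odds_ratio))

    @property
    def se_theta(self) -> float:
        return float((np.log(self.ci_high) - np.log(self.ci_low)) / (2 * Z_95))


@dataclass(frozen=True)
class FixturePair:
    """Per-SNP ratio estimates reconstructed from a published table.

    Only the ratio scale (θ, se) is recoverable from printed ORs and CIs,
    so :meth:`instruments` expresses each SNP with γ = 1 and a negligible
    exposure SE — the ratio-level representation every downstream method
    accepts.  Inputs are rounded to 2 decimals in print, so combined
    estimates carry a documented ±0.02–0.03 tolerance on the OR scale.
    """

    exposure: str
    outcome: str
    snps: tuple[FixtureSnp, ...]

    def ratio_estimates(self) -> list[RatioEstimate]:
        return [RatioEstimate(s.rsid, s.theta, s.se_theta) for s in self.snps]

    def instruments(self, sigma_x: float = 1e-6) -> list[HarmonizedInstrument]:
        return [
            HarmonizedInstrument(
                rsid=s.rsid, gamma=1.0, sigma_x=sigma_x,
                Gamma=s.theta, sigma_y=s.se_theta,
                aligned_allele=s.effect_allele,
            )
            for s in self.snps
        ]


def make_fixture_pairs() -> dict[str, FixturePair]:
    """The 16-SNP IL-18→AML and 2-SNP IL-17→stomach-cancer fixture sets."""
    def build(exposure, outcome, rows):
        return FixturePair(
            exposure=exposure,
            outcome=outcome,
            snps=tuple(FixtureSnp(*row) for row in rows),
        )

    return {
        "IL18_AML": build("IL-18", "AML", _IL18_AML_ROWS),
        "IL17_stomach": build("IL-17", "stomach_cancer", _IL17_STOMACH_ROWS),
    }


# ---------------------------------------------------------------------------
# Grid simulation
# ---------------------------------------------------------------------------

def simulate_grid(
    n_exposures: int,
    n_outcomes: int,
    base_cfg: SimulationConfig,
    effect_map: Mapping[tuple[str, str], float] | None,
    out_dir: str | Path,
    force: bool = False,
) -> tuple[list[str], list[str]]:
    """Write a directory of summary-statistics files for a synthetic grid.

    Exposures are named ``E1..``, outcomes ``O1..``; ``effect_map`` assigns
    beta_true per (exposure, outcome) pair, defaulting to 0.  Each exposure
    has its own SNP set; every outcome file covers all exposures' SNPs so
    the pipeline can harmonize any pair.  ``base_cfg.n_shared`` first SNPs
    of exposure E2 reuse E1's rsids (with E1's effects), to exercise the
    shared-instrument filter.  Truth records are written as JSON
    side-files.  Refuses a non-empty output directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (pass force=True to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    effect_map = dict(effect_map or {})

    exposures = [f"E{i + 1}" for i in range(n_exposures)]
    outcomes = [f"O{i + 1}" for i in range(n_outcomes)]
    rng = np.random.default_rng(base_cfg.seed)

    per_exposure: dict[str, dict] = {}
    start = 1
    for ei, exp_name in enumerate(exposures):
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(**{**asdict(base_cfg), "seed": seed,
                                  "beta_true": 0.0, "ld_blocks": base_cfg.ld_blocks})
        exp_assocs, _, ld, truth = simulate_pair(cfg, rsid_start=start)
        if ei == 1 and base_cfg.n_shared > 0:
            # overwrite the first n_shared SNPs with E1's, making them shared
            first = per_exposure[exposures[0]]
            n_sh = min(base_cfg.n_shared, len(first["assocs"]), len(exp_assocs))
            exp_assocs[:n_sh] = first["assocs"][:n_sh]
            for key in ("gamma", "sigma_y", "eaf"):
                truth[key][:n_sh] = first["truth"][key][:n_sh]
        per_exposure[exp_name] = {"assocs": exp_assocs, "truth": truth, "cfg": cfg}
        start += cfg.k
        _write_assocs(exp_assocs, out_dir / f"exposure_{exp_name}.tsv")
        (out_dir / f"truth_{exp_name}.json").write_text(json.dumps(truth, indent=2))

    for out_name in outcomes:
        rows: list[SnpAssociation] = []
        for exp_name in exposures:
            info = per_exposure[exp_name]
            beta = effect_map.get((exp_name, out_name), 0.0)
            truth = info["truth"]
            seed = int(rng.integers(0, 2**31 - 1))
            sub = np.random.default_rng(seed)
            gamma = np.array(truth["gamma"])
            sy = np.array(truth["sigma_y"])
            Gamma_hat = sub.normal(beta * gamma + np.array(truth["alpha"]), sy)
            pv = _pvals(Gamma_hat, sy)
            for j, a in enumerate(info["assocs"]):
                rows.append(SnpAssociation(
                    rsid=a.rsid, chrom=a.chrom, pos=a.pos,
                    effect_allele=a.effect_allele, other_allele=a.other_allele,
                    eaf=a.eaf, beta=float(Gamma_hat[j]), se=float(sy[j]),
                    pval=float(pv[j]), n=base_cfg.n_outcome))
        # shared SNPs appear once per owning exposure; deduplicate by rsid
        seen: dict[str, SnpAssociation] = {}
        for r in rows:
            seen.setdefault(r.rsid, r)
        _write_assocs(list(seen.values()), out_dir / f"outcome_{out_name}.tsv")

    return exposures, outcomes


def _write_assocs(assocs: Sequence[SnpAssociation], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "rsid": a.rsid, "chr": a.chrom, "pos": a.pos,
                "effect_allele": a.effect_allele, "other_allele": a.other_allele,
                "eaf": a.eaf, "beta": a.beta, "se": a.se, "pval": a.pval, "n": a.n,
            }
            for a in assocs
        ]
    ).to_csv(path, sep="\t", index=False)
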