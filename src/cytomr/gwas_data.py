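"""Reading, selection, pruning and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization consumes per-SNP association summaries
from two independent GWAS: one for the exposure (here, a circulating
cytokine in SD units) and one for the outcome (a binary cancer phenotype,
log-odds scale).  This module turns delimited summary-statistics text into
validated records, applies genome-wide significance selection and greedy LD
pruning, removes instruments shared between exposures, aligns exposure and
outcome effects onto a common effect allele, and quantifies instrument
strength via the explained variance R² and the F-statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cytomr")

__all__ = [
    "SnpAssociation",
    "LdTable",
    "HarmonizedInstrument",
    "InstrumentSet",
    "DropVerdict",
    "SummaryStatError",
    "DEFAULT_DIALECT",
    "read_summary_stats",
    "select_instruments",
    "ld_prune",
    "exclude_shared_snps",
    "harmonize",
    "harmonize_pairs",
    "instrument_strength",
    "per_snp_f_stats",
    "write_instruments",
]


class SummaryStatError(ValueError):
    """Raised for unusable summary-statistics input (missing columns, bad rows)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele``: log-odds
    for binary outcomes, SD units for quantitative exposures.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.rsid}: eaf must be in [0,1], got {self.eaf}")
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele are identical ({ea})")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        object.__setattr__(self, "rsid", str(self.rsid))


class LdTable:
    """Sparse symmetric table of pairwise LD r² values.

    Absent pairs are treated as unlinked (r² = 0); the diagonal is 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2({a},{b}) = {r2} outside [0,1]")
        if a == b:
            return
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def rsids(self) -> set[str]:
        out: set[str] = set()
        for pair in self._r2:
            out.update(pair)
        return out

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        """Read a long-format table with columns rsid_a, rsid_b, r2."""
        df = pd.read_csv(path, sep=None, engine="python")
        needed = {"rsid_a", "rsid_b", "r2"}
        if not needed.issubset(df.columns):
            raise SummaryStatError(f"LD table {path} must have columns {sorted(needed)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.rsid_a), str(row.rsid_b), float(row.r2))
        return table


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-SNP aligned effect pair on a common effect allele.

    ``gamma``/``sigma_x`` are the SNP→exposure effect and SE; ``Gamma``/
    ``sigma_y`` the SNP→outcome effect (log-odds) and SE, both expressed for
    ``aligned_allele``.
    """

    rsid: str
    gamma: float
    sigma_x: float
    Gamma: float
    sigma_y: float
    aligned_allele: str
    eaf: float | None = None  # exposure effect-allele frequency after alignment

    def __post_init__(self) -> None:
        if self.sigma_x <= 0:
            raise ValueError(f"{self.rsid}: sigma_x must be > 0")
        if self.sigma_y <= 0:
            raise ValueError(f"{self.rsid}: sigma_y must be > 0")


@dataclass(frozen=True)
class DropVerdict:
    """A SNP rejected during harmonization, with a machine-readable reason."""

    rsid: str
    reason: str


@dataclass
class InstrumentSet:
    """Analysis-ready instruments for one exposure–outcome pair."""

    exposure: str
    outcome: str
    instruments: list[HarmonizedInstrument]
    n_exposure: int
    r2_total: float = float("nan")
    f_stat: float = float("nan")

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ValueError("InstrumentSet requires at least one instrument")
        rsids = [i.rsid for i in self.instruments]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in instrument set")

    @property
    def k(self) -> int:
        return len(self.instruments)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

#: Default column names of the summary-statistics dialect (field -> header).
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read tab- or comma-delimited GWAS summary statistics.

    ``dialect`` maps :class:`SnpAssociation` field names to the file's column
    headers (defaults to :data:`DEFAULT_DIALECT`; only overrides need be
    given).  Rows violating a record invariant (e.g. se ≤ 0) are skipped with
    a logged row-level diagnostic; non-numeric beta or se raises
    :class:`SummaryStatError` naming the row.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [cols[f] for f in _MANDATORY if cols[f] not in df.columns]
    if missing:
        raise SummaryStatError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    out: list[SnpAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        rec = dict(zip(df.columns, row))
        try:
            beta = float(rec[cols["beta"]])
            se = float(rec[cols["se"]])
        except (TypeError, ValueError) as exc:
            raise SummaryStatError(f"{path} line {i}: non-numeric beta/se") from exc
        try:
            eaf_raw = rec.get(cols["eaf"]) if has_eaf else None
            n_raw = rec.get(cols["n"]) if has_n else None
            assoc = SnpAssociation(
                rsid=rec[cols["rsid"]],
                chrom=str(rec[cols["chrom"]]),
                pos=int(float(rec[cols["pos"]])),
                effect_allele=rec[cols["effect_allele"]],
                other_allele=rec[cols["other_allele"]],
                beta=beta,
                se=se,
                pval=float(rec[cols["pval"]]),
                eaf=None if eaf_raw in (None, "", "NA") or pd.isna(eaf_raw) else float(eaf_raw),
                n=None if n_raw in (None, "", "NA") or pd.isna(n_raw) else int(float(n_raw)),
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d rejected: %s", path, i, exc)
            continue
        out.append(assoc)
    return out


# ---------------------------------------------------------------------------
# Instrument selection and pruning
# ---------------------------------------------------------------------------

def select_instruments(
    assocs: Sequence[SnpAssociation], p_threshold: float = 5e-8
) -> list[SnpAssociation]:
    """Keep SNPs below the significance threshold (strict ``pval < p_threshold``)."""
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0,1], got {p_threshold}")
    return [a for a in assocs if a.pval < p_threshold]


def ld_prune(
    assocs: Sequence[SnpAssociation],
    ld: LdTable | None,
    r2_threshold: float = 0.1,
) -> list[SnpAssociation]:
    """Greedy LD clumping: keep the most significant SNP of each LD cluster.

    Candidates are ordered by ascending p-value (ties broken by rsid for
    determinism); each kept SNP discards all remaining SNPs with r² ≥
    ``r2_threshold`` against it.  The output preserves the order of the kept
    SNPs in the input.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError(f"r2_threshold must be in (0,1], got {r2_threshold}")
    ld = ld or LdTable()
    known = {a.rsid for a in assocs}
    orphans = ld.rsids() - known
    if orphans:
        logger.warning("LD table names %d rsid(s) absent from input; ignored", len(orphans))

    ranked = sorted(assocs, key=lambda a: (a.pval, a.rsid))
    kept: list[SnpAssociation] = []
    for cand in ranked:
        if all(ld.r2(cand.rsid, k.rsid) < r2_threshold for k in kept):
            kept.append(cand)
    kept_ids = {a.rsid for a in kept}
    return [a for a in assocs if a.rsid in kept_ids]


def exclude_shared_snps(
    per_exposure: Mapping[str, Sequence[SnpAssociation]],
) -> tuple[dict[str, list[SnpAssociation]], dict[str, list[str]]]:
    """Remove SNPs instrumenting more than one exposure from every list.

    Returns the filtered map and a map ``rsid -> exposures it appeared in``
    for the removed SNPs, so the number of removal events can be reported.
    """
    membership: dict[str, list[str]] = {}
    for exposure, assocs in per_exposure.items():
        for a in assocs:
            membership.setdefault(a.rsid, []).append(exposure)
    shared = {rsid: exps for rsid, exps in membership.items() if len(exps) > 1}
    if shared:
        logger.info("excluding %d SNP(s) shared between exposures", len(shared))
    filtered = {
        exposure: [a for a in assocs if a.rsid not in shared]
        for exposure, assocs in per_exposure.items()
    }
    return filtered, shared


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    palindrome_policy: str = "freq",
    ambiguity_bound: float = 0.42,
) -> HarmonizedInstrument | DropVerdict:
    """Align an outcome association onto the exposure's effect allele.

    Resolution order: identical alleles → copy; swapped alleles → negate the
    outcome beta (and flip its frequency); strand-complemented alleles →
    complement, then the same two rules.  Palindromic SNPs (A/T or C/G) are
    strand-ambiguous: with ``palindrome_policy="drop"`` they are removed;
    with ``"freq"`` (default) the shared minor allele identifies the
    alignment, unless either frequency is within ``ambiguity_bound`` of 0.5
    (``min(eaf, 1-eaf) >= ambiguity_bound``), in which case the SNP is
    dropped as unresolvable.
    """
    if exposure.rsid != outcome.rsid:
        raise ValueError(f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    if palindrome_policy not in ("freq", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    rsid = exposure.rsid
    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    def _build(Gamma: float) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=rsid,
            gamma=exposure.beta,
            sigma_x=exposure.se,
            Gamma=Gamma,
            sigma_y=outcome.se,
            aligned_allele=e_ea,
            eaf=exposure.eaf,
        )

    if _is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return DropVerdict(rsid, "allele_mismatch")
        if palindrome_policy == "drop":
            return DropVerdict(rsid, "palindromic")
        if exposure.eaf is None or outcome.eaf is None:
            return DropVerdict(rsid, "palindromic_no_freq")
        if (
            min(exposure.eaf, 1 - exposure.eaf) >= ambiguity_bound
            or min(outcome.eaf, 1 - outcome.eaf) >= ambiguity_bound
        ):
            return DropVerdict(rsid, "palindromic_ambiguous")
        # For a palindromic SNP a strand flip maps each allele to its label's
        # partner, so the labels carry no cross-strand information; the minor
        # allele is the only strand-safe anchor.  The labelled effect alleles
        # refer to the same physical allele iff their frequencies fall on the
        # same side of 0.5.
        aligned = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        return _build(outcome.beta if aligned else -outcome.beta)

    for flip_strand in (False, True):
        ea = _complement(o_ea) if flip_strand else o_ea
        oa = _complement(o_oa) if flip_strand else o_oa
        if (ea, oa) == (e_ea, e_oa):
            return _build(outcome.beta)
        if (ea, oa) == (e_oa, e_ea):
            return _build(-outcome.beta)
    return DropVerdict(rsid, "irreconcilable_alleles")


def harmonize_pairs(
    exposure_assocs: Sequence[SnpAssociation],
    outcome_assocs: Sequence[SnpAssociation],
    palindrome_policy: str = "freq",
    ambiguity_bound: float = 0.42,
) -> tuple[list[HarmonizedInstrument], list[DropVerdict]]:
    """Harmonize all exposure SNPs found in the outcome GWAS (matched by rsid).

    Exposure SNPs absent from the outcome data are recorded as drops with
    reason ``missing_in_outcome`` (the two GWAS sources need not share
    coverage).
    """
    by_rsid = {a.rsid: a for a in outcome_assocs}
    kept: list[HarmonizedInstrument] = []
    drops: list[DropVerdict] = []
    for exp in exposure_assocs:
        out = by_rsid.get(exp.rsid)
        if out is None:
            drops.append(DropVerdict(exp.rsid, "missing_in_outcome"))
            continue
        result = harmonize(exp, out, palindrome_policy, ambiguity_bound)
        if isinstance(result, DropVerdict):
            drops.append(result)
        else:
            kept.append(result)
    return kept, drops


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

def _per_snp_r2(
    gammas: np.ndarray,
    sigmas: np.ndarray,
    eafs: Sequence[float | None],
    n_exposure: int,
) -> np.ndarray:
    """Variance in the (unit-variance) exposure explained per SNP.

    Default estimator 2f(1−f)γ²; where the effect-allele frequency is
    missing, the beta/SE/N approximation γ²/(γ² + σ²N) is used instead.
    """
    r2 = np.empty(len(gammas))
    for j, f in enumerate(eafs):
        if f is not None and 0 < f < 1:
            r2[j] = 2 * f * (1 - f) * gammas[j] ** 2
        else:
            r2[j] = gammas[j] ** 2 / (gammas[j] ** 2 + sigmas[j] ** 2 * n_exposure)
    return r2


def instrument_strength(
    gammas: Sequence[float],
    sigmas: Sequence[float],
    eafs: Sequence[float | None] | None,
    n_exposure: int,
    formula: str = "unadjusted",
) -> tuple[float, float]:
    """Total explained variance R² and instrument-strength F for a SNP set.

    ``formula="unadjusted"`` computes F = R²(N−1−k)/(1−R²); ``"classical"`` the
    k-adjusted multi-instrument form F = [R²/k]·[(N−1−k)/(1−R²)].  The two
    differ by the factor k for k > 1; a log note is emitted in that case.
    """
    g = np.asarray(gammas, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    k = len(g)
    if k < 1:
        raise ValueError("need at least one instrument")
    if n_exposure <= k + 1:
        raise ValueError(f"sample size N={n_exposure} must exceed k+1={k + 1}")
    if eafs is None:
        eafs = [None] * k
    r2_total = float(np.sum(_per_snp_r2(g, s, eafs, n_exposure)))
    if r2_total >= 1:
        raise ValueError(f"total R² = {r2_total:.3f} >= 1; check inputs")
    f = r2_total * (n_exposure - 1 - k) / (1 - r2_total)
    if formula == "classical":
        f /= k
    elif formula != "unadjusted":
        raise ValueError(f"unknown formula {formula!r}")
    if formula == "unadjusted" and k > 1:
        logger.debug("F uses the unadjusted form (no division by k=%d)", k)
    return r2_total, f


def per_snp_f_stats(
    gammas: Sequence[float],
    sigmas: Sequence[float],
    eafs: Sequence[float | None] | None,
    n_exposure: int,
) -> np.ndarray:
    """Single-SNP F-statistics F_j = R²_j (N−2)/(1−R²_j)."""
    g = np.asarray(gammas, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if eafs is None:
        eafs = [None] * len(g)
    r2 = _per_snp_r2(g, s, eafs, n_exposure)
    return r2 * (n_exposure - 2) / (1 - r2)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_instruments(insts: Iterable[HarmonizedInstrument], path: str | Path) -> None:
    """Write harmonized instruments as TSV."""
    df = pd.DataFrame(
        [
            {
                "rsid": i.rsid,
                "gamma": i.gamma,
                "sigma_x": i.sigma_x,
                "Gamma": i.Gamma,
                "sigma_y": i.sigma_y,
                "aligned_allele": i.aligned_allele,
                "eaf": i.eaf,
            }
            for i in insts
        ]
    )
    df.to_csv(path, sep="\t", index=False)
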