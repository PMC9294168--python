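"""Leave-one-out analysis and exclusion-list reruns.

Robustness checks for the primary IVW estimate: re-estimating with each
instrument removed in turn, and re-running after removing instruments
flagged for secondary phenotypes (supplied as a user exclusion list — the
stand-in for a manual GWAS-Catalog scan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .estimators import MrEstimate, ivw, ratio_estimates
from .gwas_data import HarmonizedInstrument

logger = logging.getLogger("cytomr")

__all__ = ["LooRecord", "leave_one_out", "rerun_excluding",
           "read_exclusion_list", "write_loo_records"]


@dataclass(frozen=True)
class LooRecord:
    """IVW estimate with one named instrument excluded."""

    excluded_rsid: str
    estimate: MrEstimate


def leave_one_out(
    insts: Sequence[HarmonizedInstrument],
    model_rule: str = "auto",
    het_alpha: float = 0.05,
    se_order: str = "first",
) -> list[LooRecord]:
    """One IVW re-estimate per instrument, each on the remaining k−1 SNPs."""
    if len(insts) < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    records = []
    for i, inst in enumerate(insts):
        rest = [x for j, x in enumerate(insts) if j != i]
        est, _ = ivw(ratio_estimates(rest, se_order), model_rule, het_alpha)
        records.append(LooRecord(excluded_rsid=inst.rsid, estimate=est))
    return records


def rerun_excluding(
    insts: Sequence[HarmonizedInstrument],
    exclusion_list: Mapping[str, str] | Sequence[str],
    model_rule: str = "auto",
    het_alpha: float = 0.05,
    se_order: str = "first",
) -> tuple[MrEstimate, dict[str, str]]:
    """IVW on the instruments surviving the exclusion list.

    ``exclusion_list`` maps rsid to the stated reason (a bare sequence of
    rsids gets reason "unspecified").  Returns the estimate and the rsids
    actually dropped with their reasons; listed rsids absent from the set
    produce a warning, not an error.
    """
    if not isinstance(exclusion_list, Mapping):
        exclusion_list = {r: "unspecified" for r in exclusion_list}
    present = {i.rsid for i in insts}
    missing = set(exclusion_list) - present
    if missing:
        logger.warning("exclusion list names %d rsid(s) not in the instrument set: %s",
                       len(missing), sorted(missing))
    dropped = {r: reason for r, reason in exclusion_list.items() if r in present}
    surviving = [i for i in insts if i.rsid not in dropped]
    if not surviving:
        raise ValueError("exclusion list removes every instrument")
    est, _ = ivw(ratio_estimates(surviving, se_order), model_rule, het_alpha)
    return est, dropped


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a TSV exclusion list with columns rsid, reason."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "rsid" not in df.columns:
        raise ValueError(f"{path}: exclusion list needs an 'rsid' column")
    reasons = df["reason"] if "reason" in df.columns else ["unspecified"] * len(df)
    return dict(zip(df["rsid"], reasons))


def write_loo_records(records: Sequence[LooRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "excluded_rsid": r.excluded_rsid,
                "beta": r.estimate.beta,
                "se": r.estimate.se,
                "or": r.estimate.odds_ratio,
                "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high,
                "pval": r.estimate.pval,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
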