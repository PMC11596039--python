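"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires every instrument's exposure and outcome effects to be
expressed for the *same* effect allele.  Given an instrument list selected on
the exposure, :func:`harmonize` aligns each SNP's outcome association to the
exposure's effect allele:

* identical allele pairs in the same orientation are kept as-is;
* swapped EA/OA pairs have the outcome beta sign-flipped (and EAF mirrored);
* strand complementation (A<->T, C<->G) is attempted exactly once before a
  pair is declared incompatible;
* palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles alone:
  those with minor-allele frequency above the ambiguity cutoff (0.42) in
  either dataset are dropped, the rest are oriented by matching which side of
  0.5 the effect-allele frequency falls on.

Dropped SNPs carry a reason and never reach the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .summary_io import GwasSummary

__all__ = [
    "HARMONIZED_COLUMNS",
    "InstrumentSet",
    "is_palindromic",
    "harmonize",
    "orient_positive_exposure",
    "read_instrument_set",
    "write_instrument_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "SNP", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT",
    "EAF_EXP", "EAF_OUT", "ACTION",
]

#: actions of retained instruments
RETAINED_ACTIONS = frozenset({"aligned", "sign_flipped", "palindromic_aligned"})

#: minimum k for the Egger / median / mode estimators
MIN_K_ROBUST = 3


def is_palindromic(ea: str, oa: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


@dataclass
class InstrumentSet:
    """Exposure/outcome-aligned instruments, the input to every estimator.

    ``table`` holds one row per retained instrument with columns
    ``SNP BETA_EXP SE_EXP BETA_OUT SE_OUT EAF_EXP EAF_OUT ACTION``;
    ``dropped`` records the discarded SNPs with their reasons.
    """

    exposure_label: str
    outcome_label: str
    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "REASON"])
    )
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("no harmonizable instruments")
        if (self.table["SE_EXP"] <= 0).any() or (self.table["SE_OUT"] <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def sufficient_for_robust(self) -> bool:
        """k >= 3, required by Egger and the median/mode estimators."""
        return self.k >= MIN_K_ROBUST

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (
            t["BETA_EXP"].to_numpy(float),
            t["SE_EXP"].to_numpy(float),
            t["BETA_OUT"].to_numpy(float),
            t["SE_OUT"].to_numpy(float),
        )

    def drop_snps(self, snp_ids: Iterable[str], reason: str) -> "InstrumentSet":
        """New set without ``snp_ids`` (recorded in ``dropped``)."""
        snp_ids = set(snp_ids)
        keep = self.table[~self.table["SNP"].isin(snp_ids)]
        extra = pd.DataFrame(
            {"SNP": sorted(snp_ids), "REASON": reason}
        )
        return InstrumentSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            table=keep.reset_index(drop=True),
            dropped=pd.concat([self.dropped, extra], ignore_index=True),
            provenance=dict(self.provenance),
        )

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            table=self.table.loc[np.asarray(mask)].reset_index(drop=True),
            dropped=self.dropped,
            provenance=dict(self.provenance),
        )


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    instruments: Sequence[str],
    *,
    maf_ambiguity: float = 0.42,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    Parameters
    ----------
    instruments
        SNP ids previously selected on the exposure.
    maf_ambiguity
        Palindromic SNPs whose minor-allele frequency exceeds this value in
        either dataset are dropped as strand-ambiguous.

    Raises
    ------
    ValueError
        If no instrument survives harmonization.
    """
    instruments = list(dict.fromkeys(instruments))
    exp = exposure.records[exposure.records["SNP"].isin(instruments)]
    out = outcome.records.set_index("SNP")

    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for r in exp.itertuples(index=False):
        snp = r.SNP
        if snp not in out.index:
            dropped.append((snp, "missing_in_outcome"))
            continue
        o = out.loc[snp]
        ea_e, oa_e = r.EA, r.OA
        ea_o, oa_o = o["EA"], o["OA"]
        beta_out, eaf_out = float(o["BETA"]), float(o["EAF"])

        if is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                dropped.append((snp, "allele_mismatch"))
                continue
            maf = min(
                r.EAF, 1.0 - r.EAF, eaf_out, 1.0 - eaf_out
            )
            # the larger of the two datasets' MAFs decides ambiguity
            maf_e = min(r.EAF, 1.0 - r.EAF)
            maf_o = min(eaf_out, 1.0 - eaf_out)
            if max(maf_e, maf_o) > maf_ambiguity:
                dropped.append((snp, "palindromic_ambiguous"))
                continue
            same_side = (r.EAF < 0.5) == (eaf_out < 0.5)
            if not same_side:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            action = "palindromic_aligned"
        else:
            pair_o = (ea_o, oa_o)
            comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
            if pair_o == (ea_e, oa_e) or comp == (ea_e, oa_e):
                action = "aligned"
            elif pair_o == (oa_e, ea_e) or comp == (oa_e, ea_e):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                action = "sign_flipped"
            else:
                dropped.append((snp, "allele_mismatch"))
                continue

        rows.append(
            {
                "SNP": snp,
                "BETA_EXP": float(r.BETA),
                "SE_EXP": float(r.SE),
                "BETA_OUT": beta_out,
                "SE_OUT": float(o["SE"]),
                "EAF_EXP": float(r.EAF),
                "EAF_OUT": eaf_out,
                "ACTION": action,
            }
        )

    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    if len(table) == 0:
        raise ValueError("no harmonizable instruments")
    return InstrumentSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        table=table,
        dropped=pd.DataFrame(dropped, columns=["SNP", "REASON"]),
        provenance={"maf_ambiguity": maf_ambiguity},
    )


def orient_positive_exposure(iset: InstrumentSet) -> InstrumentSet:
    """Flip instruments so every exposure effect is non-negative.

    Both betas are negated together, leaving every Wald ratio — and hence all
    slope estimators — unchanged; only intercept-bearing models (MR-Egger)
    depend on this orientation convention.
    """
    table = iset.table.copy()
    neg = table["BETA_EXP"].to_numpy() < 0
    table.loc[neg, "BETA_EXP"] = -table.loc[neg, "BETA_EXP"]
    table.loc[neg, "BETA_OUT"] = -table.loc[neg, "BETA_OUT"]
    return InstrumentSet(
        exposure_label=iset.exposure_label,
        outcome_label=iset.outcome_label,
        table=table,
        dropped=iset.dropped,
        provenance=dict(iset.provenance),
    )


def write_instrument_set(iset: InstrumentSet, path: str | Path) -> None:
    iset.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_instrument_set(
    path: str | Path, *, exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> InstrumentSet:
    table = pd.read_csv(path, sep="\t", dtype={"SNP": str, "ACTION": str})
    return InstrumentSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        table=table[HARMONIZED_COLUMNS],
    )
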