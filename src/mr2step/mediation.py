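"""Two-step MR mediation screen with delta-method inference.

For each candidate mediator (e.g. a serum metabolite) two univariable MR
estimates are combined:

* **step 1** — exposure -> mediator, using the exposure's instruments;
* **step 2** — mediator -> outcome, using the mediator's own instruments
  (selected at 5e-8, relaxed to 5e-6 for sparsely instrumented traits).

The indirect effect is the product of coefficients ``beta1 * beta2`` with the
first-order delta-method SE ``sqrt(beta2² se1² + beta1² se2²)`` (the two
steps use disjoint instrument sets and are treated as independent).  The
proportion mediated divides the indirect by the total exposure -> outcome
effect, again with a delta-method CI.  A mediator passes the screen when both
steps are individually significant (p < 0.05); Benjamini–Hochberg q-values
over the panel are reported alongside the raw screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import Z_95, ivw
from .harmonize import harmonize
from .instruments import select_instruments
from .summary_io import GwasSummary, LdMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IndirectEffect", "MediationResult", "MEDIATION_COLUMNS",
    "indirect_effect", "proportion_mediated", "screen_mediators",
    "classify_direction", "mediation_results_frame",
]

MEDIATION_COLUMNS = [
    "MEDIATOR", "STATUS", "NSNP1", "BETA1", "SE1", "P1",
    "NSNP2", "BETA2", "SE2", "P2",
    "TOTAL", "SE_TOTAL", "INDIRECT", "SE_INDIRECT",
    "INDIRECT_L95", "INDIRECT_U95", "P_INDIRECT",
    "PM", "PM_L95", "PM_U95", "PM_OUT_OF_RANGE",
    "FDR_Q", "PASSES", "DIRECTION",
]


@dataclass
class IndirectEffect:
    indirect: float
    se: float
    ci_low: float
    ci_high: float
    pval: float


def indirect_effect(
    b1: float, se1: float, b2: float, se2: float
) -> IndirectEffect:
    """Product-of-coefficients indirect effect with delta-method CI.

    ``se = sqrt(b2² se1² + b1² se2²)`` (first-order, independent steps);
    95% CI is normal-based and the p-value two-sided normal.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("step standard errors must be positive")
    ind = b1 * b2
    se = float(np.sqrt(b2**2 * se1**2 + b1**2 * se2**2))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(ind) / se))
    else:  # both betas zero
        p = 1.0
    return IndirectEffect(
        indirect=ind, se=se,
        ci_low=ind - Z_95 * se, ci_high=ind + Z_95 * se, pval=p,
    )


def proportion_mediated(
    indirect: float, se_ind: float, total: float, se_total: float
) -> tuple[float, float, float, bool]:
    """Proportion mediated ``indirect / total`` with a delta-method CI.

    Returns ``(pm, ci_low, ci_high, out_of_range)``; estimates outside
    [0, 1] (inconsistent mediation, e.g. opposite-sign paths) are flagged,
    not rejected.
    """
    if total == 0:
        raise ValueError("total effect must be nonzero")
    pm = indirect / total
    var = se_ind**2 / total**2 + indirect**2 * se_total**2 / total**4
    half = Z_95 * float(np.sqrt(var))
    out_of_range = not 0.0 <= pm <= 1.0
    return pm, pm - half, pm + half, out_of_range


def classify_direction(beta_step2: float, p_step2: float,
                       alpha: float = 0.05) -> str:
    """Label a screened mediator by the sign of its effect on the outcome.

    ``protective`` (negative), ``risk`` (positive); ``null`` when the
    mediator -> outcome step is not significant.
    """
    if p_step2 >= alpha or beta_step2 == 0:
        return "null"
    return "protective" if beta_step2 < 0 else "risk"


@dataclass
class MediationResult:
    """One mediator's two-step MR summary (a row of the mediation table)."""

    mediator_label: str
    status: str = "ok"
    nsnp_step1: int = 0
    beta_step1: float = np.nan
    se_step1: float = np.nan
    p_step1: float = np.nan
    nsnp_step2: int = 0
    beta_step2: float = np.nan
    se_step2: float = np.nan
    p_step2: float = np.nan
    beta_total: float = np.nan
    se_total: float = np.nan
    indirect: float = np.nan
    se_indirect: float = np.nan
    ci_indirect: tuple[float, float] = (np.nan, np.nan)
    p_indirect: float = np.nan
    pm: float = np.nan
    pm_ci: tuple[float, float] = (np.nan, np.nan)
    pm_out_of_range: bool = False
    passes_screen: bool = False
    fdr_q: float = np.nan
    direction: str = "null"


def _mediation_row(res: MediationResult) -> dict:
    return {
        "MEDIATOR": res.mediator_label, "STATUS": res.status,
        "NSNP1": res.nsnp_step1, "BETA1": res.beta_step1,
        "SE1": res.se_step1, "P1": res.p_step1,
        "NSNP2": res.nsnp_step2, "BETA2": res.beta_step2,
        "SE2": res.se_step2, "P2": res.p_step2,
        "TOTAL": res.beta_total, "SE_TOTAL": res.se_total,
        "INDIRECT": res.indirect, "SE_INDIRECT": res.se_indirect,
        "INDIRECT_L95": res.ci_indirect[0], "INDIRECT_U95": res.ci_indirect[1],
        "P_INDIRECT": res.p_indirect,
        "PM": res.pm, "PM_L95": res.pm_ci[0], "PM_U95": res.pm_ci[1],
        "PM_OUT_OF_RANGE": res.pm_out_of_range,
        "FDR_Q": res.fdr_q, "PASSES": res.passes_screen,
        "DIRECTION": res.direction,
    }


def mediation_results_frame(results: list[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame([_mediation_row(r) for r in results],
                        columns=MEDIATION_COLUMNS)


def screen_mediators(
    exposure: GwasSummary,
    outcome: GwasSummary,
    panel: list[GwasSummary],
    ld: LdMatrix,
    *,
    p_threshold: float = 5e-8,
    relaxed_threshold: float = 5e-6,
    relaxed_min_snps: int = 4,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    f_min: float = 10.0,
    maf_ambiguity: float = 0.42,
    alpha: float = 0.05,
) -> list[MediationResult]:
    """Run the two-step mediation screen over a mediator panel.

    The total effect (exposure -> outcome, IVW-MRE) is computed once; each
    mediator then contributes a step-1 estimate on the exposure's instruments
    and a step-2 estimate on its own instruments harmonized against the
    outcome.  Mediators without usable step-2 instruments get status
    ``no_instruments`` and are excluded from the FDR.  Results are sorted by
    the step-2 p-value; the output is invariant to panel ordering.
    """
    if len(panel) == 0:
        logger.warning("empty mediator panel: nothing to screen")
        return []

    exp_iv, _ = select_instruments(
        exposure, ld, p_threshold=p_threshold, relaxed_threshold=None,
        clump_r2=clump_r2, clump_kb=clump_kb, f_min=f_min,
    )
    exp_snps = exp_iv["SNP"].tolist()
    total_set = harmonize(exposure, outcome, exp_snps,
                          maf_ambiguity=maf_ambiguity)
    total = ivw(total_set, "mre")

    results: list[MediationResult] = []
    for med in panel:
        res = MediationResult(mediator_label=med.trait_label)
        res.beta_total, res.se_total = total.beta, total.se
        try:
            step1_set = harmonize(exposure, med, exp_snps,
                                  maf_ambiguity=maf_ambiguity)
            step1 = ivw(step1_set, "mre")
        except ValueError:
            res.status = "no_instruments"
            results.append(res)
            continue
        res.nsnp_step1 = step1.nsnp
        res.beta_step1, res.se_step1 = step1.beta, step1.se
        res.p_step1 = step1.pval

        med_iv, _ = select_instruments(
            med, ld, p_threshold=p_threshold,
            relaxed_threshold=relaxed_threshold,
            relaxed_min_snps=relaxed_min_snps,
            clump_r2=clump_r2, clump_kb=clump_kb, f_min=f_min,
        )
        if len(med_iv) < 2:
            res.status = "no_instruments"
            results.append(res)
            continue
        try:
            step2_set = harmonize(med, outcome, med_iv["SNP"].tolist(),
                                  maf_ambiguity=maf_ambiguity)
            step2 = ivw(step2_set, "mre")
        except ValueError:
            res.status = "no_instruments"
            results.append(res)
            continue
        res.nsnp_step2 = step2.nsnp
        res.beta_step2, res.se_step2 = step2.beta, step2.se
        res.p_step2 = step2.pval

        ind = indirect_effect(res.beta_step1, res.se_step1,
                              res.beta_step2, res.se_step2)
        res.indirect, res.se_indirect = ind.indirect, ind.se
        res.ci_indirect = (ind.ci_low, ind.ci_high)
        res.p_indirect = ind.pval
        pm, lo, hi, oob = proportion_mediated(
            ind.indirect, ind.se, total.beta, total.se
        )
        res.pm, res.pm_ci, res.pm_out_of_range = pm, (lo, hi), oob
        res.passes_screen = res.p_step1 < alpha and res.p_step2 < alpha
        res.direction = classify_direction(res.beta_step2, res.p_step2, alpha)
        results.append(res)

    scored = [r for r in results if r.status == "ok"]
    if scored:
        qvals = multipletests(
            [r.p_step2 for r in scored], method="fdr_bh"
        )[1]
        for r, q in zip(scored, qvals):
            r.fdr_q = float(q)
    results.sort(
        key=lambda r: (np.isnan(r.p_step2), r.p_step2, r.mediator_label)
    )
    return results
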