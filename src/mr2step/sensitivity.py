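"""Heterogeneity, pleiotropy and outlier diagnostics for MR results.

Covers the standard sensitivity suite: Cochran's Q (on the IVW and the
MR-Egger basis), the Egger intercept test for directional pleiotropy,
leave-one-out re-estimation, and a simulation-based residual-sum test
(MR-PRESSO) with per-SNP outlier identification.  Plot-ready scatter,
funnel and forest tables are exported as TSV; no figures are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, egger, ivw
from .harmonize import InstrumentSet

__all__ = [
    "HeterogeneityResult", "PressoResult",
    "cochran_q", "egger_intercept_test", "leave_one_out", "mr_presso",
    "export_plot_tables",
]


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test on one regression basis."""

    basis: str  # "ivw" | "egger"
    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """Global residual-sum pleiotropy test plus per-SNP outlier calls."""

    rss_observed: float
    global_pval: float
    outlier_pvals: pd.DataFrame  # SNP, RSS_OBS, PVAL, PVAL_BONF
    outliers: list[str]
    n_sim: int
    seed: int


def cochran_q(iset: InstrumentSet, basis: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q about the IVW-fixed mean (df = k-1) or the Egger fit
    (df = k-2), with an upper-tail chi-square p."""
    k = iset.k
    if basis == "ivw":
        if k < 2:
            raise ValueError("Q (ivw basis) requires k >= 2")
        est = ivw(iset, "fixed")
        q = est.extras["Q"]
        df = k - 1
    elif basis == "egger":
        if k < 3:
            raise ValueError("Q (egger basis) requires k >= 3")
        slope, intercept = egger(iset)
        bx, _, by, sy = iset.arrays()
        # Q must be evaluated in the same orientation the fit used
        flip = np.where(bx < 0, -1.0, 1.0)
        resid = by * flip - intercept.beta - slope.beta * bx * flip
        q = float(np.sum(resid**2 / sy**2))
        df = k - 2
    else:
        raise ValueError(f"unknown basis {basis!r}")
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(basis=basis, Q=q, df=df, pval=pval)


def egger_intercept_test(iset: InstrumentSet) -> MrEstimate:
    """The MR-Egger intercept as a standalone pleiotropy diagnostic."""
    _, intercept = egger(iset)
    return intercept


def leave_one_out(iset: InstrumentSet) -> pd.DataFrame:
    """IVW-MRE re-estimated with each instrument omitted in turn.

    Returns k omission rows plus a final ``(all)`` row with the full-set
    estimate, for forest-plot style influence checks.
    """
    k = iset.k
    if k < 3:
        raise ValueError("leave-one-out requires k >= 3")
    rows = []
    snps = iset.table["SNP"].to_numpy()
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        est = ivw(iset.subset(mask), "mre")
        rows.append({"SNP": snps[j], "BETA": est.beta, "SE": est.se,
                     "PVAL": est.pval})
    full = ivw(iset, "mre")
    rows.append({"SNP": "(all)", "BETA": full.beta, "SE": full.se,
                 "PVAL": full.pval})
    return pd.DataFrame(rows, columns=["SNP", "BETA", "SE", "PVAL"])


def _loo_ivw_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Leave-one-out fixed-effects IVW slope for every SNP, vectorized.

    Works on 2-D inputs of shape (n_sim, k) as well as 1-D (k,).
    """
    w = bx**2 / sy**2
    theta = by / bx
    sw = np.sum(w, axis=-1, keepdims=True)
    swt = np.sum(w * theta, axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def mr_presso(
    iset: InstrumentSet, n_sim: int = 1000, seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Residual-sum global pleiotropy test with per-SNP outlier search.

    The observed statistic is the weighted residual sum of squares of each
    outcome effect about its leave-one-out IVW prediction.  Its null
    distribution is built from ``n_sim`` seeded parametric simulations that
    redraw both effect columns from their sampling distributions under the
    no-pleiotropy model; p-values carry a pseudo-count so they are never 0
    and have resolution 1/(n_sim+1).  Per-SNP outlier p-values are
    Bonferroni-multiplied by k; SNPs below ``outlier_alpha`` are reported as
    outliers.
    """
    k = iset.k
    if k < 4:
        raise ValueError("MR-PRESSO requires k >= 4 instruments")
    bx, sx, by, sy = iset.arrays()
    theta_loo = _loo_ivw_matrix(bx, by, sy)
    resid_obs = (by - theta_loo * bx) ** 2 / sy**2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    theta_loo_sim = _loo_ivw_matrix(bx_sim, by_sim, sy)
    resid_sim = (by_sim - theta_loo_sim * bx_sim) ** 2 / sy**2
    rss_sim = np.sum(resid_sim, axis=1)

    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    p_snp = (1.0 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1.0)
    p_bonf = np.minimum(1.0, p_snp * k)
    snps = iset.table["SNP"].tolist()
    table = pd.DataFrame({
        "SNP": snps, "RSS_OBS": resid_obs,
        "PVAL": p_snp, "PVAL_BONF": p_bonf,
    })
    outliers = [s for s, p in zip(snps, p_bonf) if p < outlier_alpha]
    return PressoResult(
        rss_observed=rss_obs, global_pval=float(global_pval),
        outlier_pvals=table, outliers=outliers, n_sim=n_sim, seed=seed,
    )


def export_plot_tables(
    iset: InstrumentSet,
    estimates: pd.DataFrame,
    loo: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write scatter / funnel / forest data tables (TSV; no rendering).

    scatter: per-SNP effect pairs with SEs; funnel: Wald ratios against
    their precisions 1/se; forest tables: leave-one-out rows and the method
    panel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bx, sx, by, sy = iset.arrays()
    scatter = pd.DataFrame({
        "SNP": iset.table["SNP"], "BETA_EXP": bx, "SE_EXP": sx,
        "BETA_OUT": by, "SE_OUT": sy,
    })
    ratio = by / bx
    ratio_se = sy / np.abs(bx)
    funnel = pd.DataFrame({
        "SNP": iset.table["SNP"], "RATIO": ratio,
        "PRECISION": 1.0 / ratio_se,
    })
    paths = {
        "scatter": out_dir / "scatter.tsv",
        "funnel": out_dir / "funnel.tsv",
        "forest_loo": out_dir / "forest_loo.tsv",
        "forest_methods": out_dir / "forest_methods.tsv",
    }
    scatter.to_csv(paths["scatter"], sep="\t", index=False,
                   float_format="%.17g")
    funnel.to_csv(paths["funnel"], sep="\t", index=False,
                  float_format="%.17g")
    loo.to_csv(paths["forest_loo"], sep="\t", index=False,
               float_format="%.17g")
    estimates.to_csv(paths["forest_methods"], sep="\t", index=False,
                     float_format="%.17g")
    return paths
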