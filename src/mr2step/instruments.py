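"""Instrumental-variable selection from exposure summary statistics.

Selection follows the standard two-sample MR recipe: keep genome-wide
significant SNPs (p < 5e-8; a relaxed 5e-6 cutoff is available for weakly
instrumented traits such as single metabolites), greedily clump them so
retained instruments are approximately independent (r² < 0.001 within a
10,000 kb window), and exclude weak instruments by the Staiger–Stock rule
(per-SNP F < 10).  Per-SNP variance explained uses
``R² = 2 β² EAF (1 − EAF)`` (standardized effects) and
``F = R²/(1 − R²) × (N − k − 1)/k``.

A local confounder-catalogue scan stands in for web-based lookups: instruments
in strong LD (r² > 0.1) with a catalogued trait association within 500 kb are
flagged — reported, never auto-dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_io import GwasSummary, LdMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GENOME_WIDE_P", "RELAXED_P", "CLUMP_R2", "CLUMP_KB", "F_MIN",
    "significance_filter", "clump", "variance_explained", "f_statistic",
    "annotate_strength", "weak_filter", "set_f_statistic",
    "read_confounder_catalogue", "confounder_scan", "select_instruments",
]

GENOME_WIDE_P = 5e-8
RELAXED_P = 5e-6
CLUMP_R2 = 0.001
CLUMP_KB = 10_000
F_MIN = 10.0

CATALOGUE_COLUMNS = ["SNP", "CHR", "POS", "TRAIT", "R2"]


def significance_filter(gwas: GwasSummary, p_threshold: float) -> pd.DataFrame:
    """Records with p strictly below the threshold, ascending in p.

    Ties in p are broken by (CHR, POS) so the ordering — and everything
    downstream of it — is deterministic.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0,1), got {p_threshold}")
    hits = gwas.records[gwas.records["P"] < p_threshold]
    hits = hits.sort_values(["P", "CHR", "POS"], kind="mergesort")
    return hits.reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld: LdMatrix,
    r2_max: float = CLUMP_R2,
    window_kb: float = CLUMP_KB,
) -> pd.DataFrame:
    """Greedy LD clumping of significance-filtered candidates.

    Repeatedly keeps the lowest-p remaining candidate as the index SNP and
    removes every other candidate on the same chromosome within
    ``window_kb`` kilobases whose r² with the index is >= ``r2_max`` (both
    the distance and the LD condition are required for removal).  Pairs
    absent from ``ld`` count as r² = 0.  The result is returned in ascending
    p and is independent of the input ordering.
    """
    if len(candidates) == 0:
        return candidates.reset_index(drop=True)
    df = candidates.sort_values(
        ["P", "CHR", "POS"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    snp = df["SNP"].to_numpy()
    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy(dtype=float)
    kept = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        near = (
            alive
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        near[i] = False
        for j in np.nonzero(near)[0]:
            if ld.r2(snp[i], snp[j]) >= r2_max:
                alive[j] = False
    return df.iloc[kept].reset_index(drop=True)


def variance_explained(beta, eaf):
    """Per-SNP variance in the exposure explained: ``2 β² EAF (1 − EAF)``."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise ValueError("eaf must lie in (0,1)")
    return 2.0 * beta**2 * eaf * (1.0 - eaf)


def f_statistic(r2_total, n, k: int = 1):
    """Instrument-strength F: ``R²/(1 − R²) × (N − k − 1)/k``."""
    r2_total = np.asarray(r2_total, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2_total < 0.0) | (r2_total >= 1.0)):
        raise ValueError("r2_total must lie in [0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any(n <= k + 1):
        raise ValueError("sample size must exceed k + 1")
    return r2_total / (1.0 - r2_total) * (n - k - 1.0) / k


def annotate_strength(candidates: pd.DataFrame) -> pd.DataFrame:
    """Attach per-SNP ``R2_EXPLAINED`` and ``F_STAT`` (k = 1) columns."""
    df = candidates.copy()
    r2 = variance_explained(df["BETA"], df["EAF"])
    df["R2_EXPLAINED"] = r2
    df["F_STAT"] = f_statistic(r2, df["N"].to_numpy(), k=1)
    return df


def weak_filter(candidates: pd.DataFrame, f_min: float = F_MIN) -> pd.DataFrame:
    """Drop weak instruments (per-SNP F < ``f_min``, Staiger–Stock rule).

    The boundary F = f_min is retained.  Computes strength columns if absent.
    """
    df = candidates
    if "F_STAT" not in df.columns:
        df = annotate_strength(df)
    kept = df[df["F_STAT"] >= f_min].reset_index(drop=True)
    n_weak = len(df) - len(kept)
    if n_weak:
        logger.warning("excluded %d weak instrument(s) with F < %g",
                       n_weak, f_min)
    if len(kept) == 0:
        logger.warning("all candidate instruments are weak (F < %g)", f_min)
    return kept


def set_f_statistic(candidates: pd.DataFrame) -> float:
    """Set-level F using the summed variance explained and k = |set|."""
    df = candidates
    if "R2_EXPLAINED" not in df.columns:
        df = annotate_strength(df)
    k = len(df)
    if k == 0:
        return float("nan")
    r2_total = float(df["R2_EXPLAINED"].sum())
    n = float(df["N"].min())
    return float(f_statistic(min(r2_total, 1.0 - 1e-12), n, k=k))


def read_confounder_catalogue(path: str | Path) -> pd.DataFrame:
    """Read a local confounder catalogue (``SNP CHR POS TRAIT R2``)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str,
                                            "TRAIT": str})
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"confounder catalogue missing column(s): {', '.join(missing)}"
        )
    if ((df["R2"] < 0) | (df["R2"] > 1)).any():
        raise ValueError("catalogue R2 out of range [0,1]")
    return df[CATALOGUE_COLUMNS]


def confounder_scan(
    candidates: pd.DataFrame,
    catalogue: pd.DataFrame,
    ld: LdMatrix | None = None,
    r2_min: float = 0.1,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Flag instruments linked to catalogued confounder traits.

    A candidate is flagged with a catalogue row's trait when that row lies
    within ``window_bp`` on the same chromosome and the pair's r² — from
    ``ld`` when available, else the catalogue's own ``R2`` link — exceeds
    ``r2_min``.  Flags are advisory: nothing is dropped here.
    """
    flags = []
    for r in candidates.itertuples(index=False):
        near = catalogue[
            (catalogue["CHR"].astype(str) == str(r.CHR))
            & ((catalogue["POS"] - r.POS).abs() <= window_bp)
        ]
        for c in near.itertuples(index=False):
            if ld is not None and ld.has_pair(r.SNP, c.SNP):
                r2 = ld.r2(r.SNP, c.SNP)
            else:
                r2 = float(c.R2)
            if r2 > r2_min:
                flags.append(
                    {"SNP": r.SNP, "CONFOUNDER_SNP": c.SNP,
                     "TRAIT": c.TRAIT, "R2": r2}
                )
    return pd.DataFrame(flags, columns=["SNP", "CONFOUNDER_SNP", "TRAIT", "R2"])


def select_instruments(
    gwas: GwasSummary,
    ld: LdMatrix,
    *,
    p_threshold: float = GENOME_WIDE_P,
    relaxed_threshold: float | None = RELAXED_P,
    relaxed_min_snps: int = 4,
    clump_r2: float = CLUMP_R2,
    clump_kb: float = CLUMP_KB,
    f_min: float = F_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Full selection: significance -> clump -> strength filter.

    If fewer than ``relaxed_min_snps`` SNPs pass the primary threshold after
    clumping and strength filtering, selection is repeated once at
    ``relaxed_threshold`` (the policy used for sparsely instrumented
    metabolite traits).  Returns the selected candidates plus an attrition
    dictionary of per-stage counts.
    """

    def _run(threshold: float) -> tuple[pd.DataFrame, dict]:
        sig = significance_filter(gwas, threshold)
        clumped = clump(sig, ld, r2_max=clump_r2, window_kb=clump_kb)
        strong = weak_filter(clumped, f_min=f_min)
        att = {
            "p_threshold": threshold,
            "n_total": gwas.n_records,
            "n_significant": len(sig),
            "n_clumped": len(clumped),
            "n_strong": len(strong),
        }
        return strong, att

    selected, attrition = _run(p_threshold)
    if relaxed_threshold is not None and len(selected) < relaxed_min_snps:
        relaxed_selected, relaxed_att = _run(relaxed_threshold)
        if len(relaxed_selected) > len(selected):
            relaxed_att["relaxed"] = True
            return relaxed_selected, relaxed_att
    attrition["relaxed"] = False
    return selected, attrition
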