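"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized :class:`~mr2step.harmonize.InstrumentSet`
and operate on the per-SNP Wald ratios ``theta_j = beta_out_j / beta_exp_j``
with first-order inverse-variance weights ``w_j = beta_exp_j² / se_out_j²``:

* **IVW** — weighted mean of the ratios; the multiplicative-random-effects
  (MRE) variant inflates the fixed-effects SE by ``max(1, sqrt(Q/(k-1)))``
  so over-dispersion widens, and under-dispersion never narrows, the CI.
* **MR-Egger** — weighted regression of outcome on exposure effects with a
  free intercept; a nonzero intercept estimates directional pleiotropy.
  Inference is on t(k-2) with the residual scale floored at 1.
* **Weighted median** — the 50% point of the weight-ordered ratios; consistent
  when valid instruments carry a majority of the weight.
* **Simple/weighted mode** — argmax of a Gaussian kernel density over the
  ratios (Silverman bandwidth); consistent when the largest cluster of
  instruments is valid.
* **Maximum likelihood** — joint normal measurement model for the exposure
  and outcome effects with a shared causal slope, profiled over the per-SNP
  true exposure effects.

Median and mode SEs come from a seeded parametric bootstrap of the ratios.
Effects are on the log-odds scale; ``odds_ratio = exp(beta)`` with
exponentiated CI bounds, matching the reporting convention of case/control
outcome GWAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .harmonize import InstrumentSet, orient_positive_exposure

__all__ = [
    "Z_95", "MrEstimate", "ConvergenceError",
    "wald_ratio", "ivw", "egger", "weighted_median", "mode_estimate",
    "max_likelihood", "estimate_all", "ESTIMATE_COLUMNS",
]

#: two-sided 95% normal quantile used for confidence intervals
Z_95 = 1.959964

ESTIMATE_COLUMNS = [
    "METHOD", "NSNP", "BETA", "SE", "OR", "OR_L95", "OR_U95", "PVAL", "STATUS",
]

#: Table-style method labels, in reporting order
METHOD_LABELS = {
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "ivw_mre": "Inverse variance weighted",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
    "max_likelihood": "Maximum likelihood",
}


class ConvergenceError(RuntimeError):
    """An iterative estimator failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class MrEstimate:
    """One causal estimate: a row of the MR results table."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, nsnp: int,
        *, dist: str = "norm", df: int | None = None, extras: dict | None = None,
    ) -> "MrEstimate":
        """Build an estimate with CI and p under the reference distribution.

        ``dist="norm"`` uses z = 1.959964 and a two-sided normal p;
        ``dist="t"`` uses the t(df) quantile and two-sided t p.
        """
        beta = float(beta)
        se = float(se)
        if se > 0:
            stat = beta / se
            if dist == "t":
                crit = float(stats.t.ppf(0.975, df))
                p = float(2.0 * stats.t.sf(abs(stat), df))
            else:
                crit = Z_95
                p = float(2.0 * stats.norm.sf(abs(stat)))
        else:  # degenerate (exact-fit) data
            crit, p = Z_95, (1.0 if beta == 0 else 0.0)
        p = min(max(p, 5e-324), 1.0)
        return cls(
            method=method, beta=beta, se=se,
            ci_low=beta - crit * se, ci_high=beta + crit * se,
            pval=p, nsnp=nsnp, extras=extras or {},
        )


def _ratios_weights(iset: InstrumentSet):
    bx, sx, by, sy = iset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; cannot form Wald ratio")
    theta = by / bx
    ratio_se = sy / np.abs(bx)
    w = bx**2 / sy**2  # = 1 / ratio_se**2
    return theta, ratio_se, w


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float,
    *, second_order: bool = False,
) -> MrEstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    The default SE is first-order (``se_out / |beta_exp|``); the
    second-order option also propagates the exposure uncertainty.
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    beta = beta_out / beta_exp
    if second_order:
        se = math.sqrt(
            se_out**2 / beta_exp**2
            + beta_out**2 * se_exp**2 / beta_exp**4
        )
    else:
        se = se_out / abs(beta_exp)
    return MrEstimate.from_beta_se("wald_ratio", beta, se, nsnp=1)


def cochran_q_statistic(theta: np.ndarray, w: np.ndarray) -> float:
    """Cochran's Q of the ratios about their fixed-effects IVW mean."""
    beta = float(np.sum(w * theta) / np.sum(w))
    return float(np.sum(w * (theta - beta) ** 2))


def ivw(iset: InstrumentSet, effects_model: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate (fixed or multiplicative random
    effects).

    MRE multiplies the fixed-effects SE by ``max(1, sqrt(Q/(k-1)))``; the
    floor means homogeneous sets fall back to fixed-effects precision.
    """
    if effects_model not in ("fixed", "mre"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    k = iset.k
    if k < 2:
        raise ValueError(f"IVW requires k >= 2 instruments, got {k}")
    theta, _, w = _ratios_weights(iset)
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = cochran_q_statistic(theta, w)
    scale = max(1.0, math.sqrt(q / (k - 1))) if effects_model == "mre" else 1.0
    return MrEstimate.from_beta_se(
        f"ivw_{effects_model}", beta, se_fixed * scale, nsnp=k,
        extras={"Q": q, "scale": scale, "se_fixed": se_fixed},
    )


def egger(iset: InstrumentSet) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Weighted least squares of ``beta_out`` on ``beta_exp`` with a free
    intercept and weights ``1/se_out²``, after orienting every instrument to
    a positive exposure effect (the intercept is only identified under a
    fixed orientation).  Coefficient SEs use the residual scale floored at 1
    and t(k-2) inference.
    """
    k = iset.k
    if k < 3:
        raise ValueError(f"MR-Egger requires k >= 3 instruments, got {k}")
    oriented = orient_positive_exposure(iset)
    bx, _, by, sy = oriented.arrays()
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    scale = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, scale)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    extras = {
        "intercept": float(coef[0]), "intercept_se": se_int,
        "residual_scale": scale, "df": k - 2,
    }
    slope = MrEstimate.from_beta_se(
        "egger", coef[1], se_slope, nsnp=k, dist="t", df=k - 2, extras=extras,
    )
    intercept = MrEstimate.from_beta_se(
        "egger_intercept", coef[0], se_int, nsnp=k, dist="t", df=k - 2,
    )
    slope.extras["intercept_pval"] = intercept.pval
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50% point of the weight-ordered ratios."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ws = w[order]
    s = (np.cumsum(ws) - 0.5 * ws) / np.sum(ws)
    return float(np.interp(0.5, s, th))


def _parametric_bootstrap_se(
    point_fn, theta: np.ndarray, ratio_se: np.ndarray,
    n_boot: int, seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, ratio_se, size=(n_boot, theta.size))
    ests = np.array([point_fn(draws[b]) for b in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(
    iset: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimator (majority-valid robust)."""
    k = iset.k
    if k < 3:
        raise ValueError(f"weighted median requires k >= 3, got {k}")
    theta, ratio_se, w = _ratios_weights(iset)
    beta = _weighted_median_point(theta, w)
    se = _parametric_bootstrap_se(
        lambda th: _weighted_median_point(th, w), theta, ratio_se,
        n_boot, seed,
    )
    return MrEstimate.from_beta_se(
        "weighted_median", beta, se, nsnp=k,
        extras={"n_boot": n_boot, "seed": seed},
    )


def _silverman_bandwidth(theta: np.ndarray) -> float:
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * theta.size ** (-0.2)


def _mode_point(theta: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    h = bandwidth_factor * _silverman_bandwidth(theta)
    if h <= 0 or not np.isfinite(h):  # all ratios identical
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    z = (grid[:, None] - theta[None, :]) / h
    density = np.exp(-0.5 * z**2) @ (w / np.sum(w))
    return float(grid[np.argmax(density)])


def mode_estimate(
    iset: InstrumentSet, weighted: bool = True,
    bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0,
) -> MrEstimate:
    """Mode-based estimator: argmax of a Gaussian KDE over the ratios.

    ``weighted=False`` gives the simple mode (uniform kernel weights);
    ``weighted=True`` weights each ratio by its IVW weight.  The bandwidth is
    ``bandwidth_factor`` times Silverman's rule on the ratio scale, the
    argmax is taken over a 512-point grid spanning the ratios ± 3 bandwidths,
    and the SE is a seeded parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    k = iset.k
    if k < 3:
        raise ValueError(f"mode estimator requires k >= 3, got {k}")
    theta, ratio_se, w = _ratios_weights(iset)
    kernel_w = w if weighted else np.ones(k)
    beta = _mode_point(theta, kernel_w, bandwidth_factor)
    se = _parametric_bootstrap_se(
        lambda th: _mode_point(th, kernel_w, bandwidth_factor),
        theta, ratio_se, n_boot, seed,
    )
    method = "weighted_mode" if weighted else "simple_mode"
    return MrEstimate.from_beta_se(
        method, beta, se, nsnp=k,
        extras={"n_boot": n_boot, "seed": seed,
                "bandwidth_factor": bandwidth_factor},
    )


def _ml_profile_objective(bx, sx, by, sy):
    """Profile -2·log-likelihood in the causal slope.

    The per-SNP true exposure effects are profiled out analytically: for a
    given slope θ the residual ``by - θ·bx`` is normal with variance
    ``sy² + θ²·sx²``.
    """

    def g(theta: float) -> float:
        return float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))

    return g


def max_likelihood(iset: InstrumentSet, max_iter: int = 200) -> MrEstimate:
    """Bivariate-normal maximum-likelihood estimate of the causal slope.

    Model: ``beta_exp_j ~ N(mu_j, se_exp_j²)``,
    ``beta_out_j ~ N(theta·mu_j, se_out_j²)`` with free ``mu_j``; the slope is
    found by minimizing the profile objective from the IVW-fixed start, and
    its SE comes from the observed information (numerical second derivative
    of the profile log-likelihood).
    """
    k = iset.k
    if k < 2:
        raise ValueError(f"maximum likelihood requires k >= 2, got {k}")
    bx, sx, by, sy = iset.arrays()
    g = _ml_profile_objective(bx, sx, by, sy)
    theta0 = ivw(iset, "fixed").beta
    res = optimize.minimize(
        g, x0=np.array([theta0]), method="BFGS",
        options={"maxiter": max_iter},
    )
    theta_hat = float(res.x[0])
    improved = g(theta_hat) <= g(theta0) + 1e-12
    if not (res.success or improved):
        raise ConvergenceError(
            "maximum-likelihood slope failed to converge",
            diagnostics={"message": res.message, "nit": res.nit,
                         "theta0": theta0, "theta": theta_hat},
        )
    # observed information of the profile log-likelihood: I = g''/2
    h = 1e-5 * max(1.0, abs(theta_hat))
    second = (g(theta_hat + h) - 2.0 * g(theta_hat) + g(theta_hat - h)) / h**2
    if second <= 0:
        raise ConvergenceError(
            "non-positive curvature at the ML optimum",
            diagnostics={"theta": theta_hat, "curvature": second},
        )
    se = math.sqrt(2.0 / second)
    return MrEstimate.from_beta_se(
        "max_likelihood", theta_hat, se, nsnp=k,
        extras={"objective": g(theta_hat), "n_iter": int(res.nit)},
    )


def estimate_all(
    iset: InstrumentSet, seed: int = 0, n_boot: int = 1000,
) -> pd.DataFrame:
    """Run the full estimator panel; one labelled row per method.

    Row order mirrors the reporting convention (MR Egger, weighted median,
    IVW, simple mode, weighted mode, maximum likelihood).  With k < 3 the
    robust methods are flagged ``insufficient_snps`` instead of estimated.
    """
    calls = {
        "egger": lambda: egger(iset)[0],
        "weighted_median": lambda: weighted_median(iset, n_boot, seed),
        "ivw_mre": lambda: ivw(iset, "mre"),
        "simple_mode": lambda: mode_estimate(
            iset, weighted=False, n_boot=n_boot, seed=seed + 1),
        "weighted_mode": lambda: mode_estimate(
            iset, weighted=True, n_boot=n_boot, seed=seed + 2),
        "max_likelihood": lambda: max_likelihood(iset),
    }
    needs_three = {"egger", "weighted_median", "simple_mode", "weighted_mode"}
    rows = []
    for key, call in calls.items():
        if key in needs_three and iset.k < 3:
            rows.append({
                "METHOD": METHOD_LABELS[key], "NSNP": iset.k,
                "BETA": np.nan, "SE": np.nan, "OR": np.nan,
                "OR_L95": np.nan, "OR_U95": np.nan, "PVAL": np.nan,
                "STATUS": "insufficient_snps",
            })
            continue
        est = call()
        or_l, or_u = est.or_ci
        rows.append({
            "METHOD": METHOD_LABELS[key], "NSNP": est.nsnp,
            "BETA": est.beta, "SE": est.se, "OR": est.odds_ratio,
            "OR_L95": or_l, "OR_U95": or_u, "PVAL": est.pval,
            "STATUS": "ok",
        })
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
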