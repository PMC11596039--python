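"""Synthetic GWAS summary statistics under a known causal model.

The generator emulates the statistical structure of a disease -> metabolite ->
disease-complication study: an instrumented binary-style exposure (think type 1
diabetes), a panel of serum-metabolite mediators, and an outcome (cataract),
all observed only through summary statistics.  The causal model for SNP *j*:

* exposure effect ``gamma_j`` — nonzero for the first ``m_instruments`` SNPs,
  drawn ``Normal(mu_gamma, sigma_gamma^2)`` on the exposure-raising allele;
* mediator *i* effect ``gamma_j * beta1_i + delta_ij`` where ``delta_ij`` is a
  direct effect carried by the mediator's own instrument SNPs;
* outcome effect
  ``gamma_j * (theta_direct + sum_i beta1_i * beta2_i) + sum_i delta_ij * beta2_i + alpha_j``
  where ``alpha_j`` is horizontal pleiotropy
  (``Normal(mu_alpha, sigma_alpha^2)`` for the invalid fraction, else 0).

Observed effects add sampling noise ``Normal(0, se^2)`` with the
standardized-trait standard error ``se = 1 / sqrt(2 * n * EAF * (1 - EAF))``;
this choice keeps the variance-explained formula ``R^2 = 2 beta^2 EAF (1-EAF)``
and the F-statistic internally consistent.  LD is emulated at the level of a
shared causal signal within blocks (scaled by ``sqrt(r2_within)``) plus the
reported pairwise r² matrix — enough to exercise clumping without simulating
genotypes.  A fixed seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HARMONIZED_COLUMNS, InstrumentSet
from .summary_io import (
    GwasSummary,
    LdMatrix,
    validate_gwas_frame,
    write_gwas_summary,
    write_ld_matrix,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "SimulatedStudy",
    "simulate_scenario",
    "simulate_instrument_set",
    "binary_outcome_se",
    "write_scenario",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_TINY_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults describe the package's reference scenario: 200 SNPs of which 60
    instrument the exposure, GWAS sample sizes of 200,000, a direct causal
    effect of 0.05 (log-odds per SD of exposure liability), no pleiotropy, no
    LD, and a 10% sprinkling of palindromic variants.  Instrument effects are
    Normal(0.05, 0.01^2) on the exposure-raising allele; mediator instruments
    default to 12 per mediator, the median metabolite instrument count in the
    motivating study design.
    """

    m_snps: int = 200
    m_instruments: int = 60
    m_outcome_snps: int = 60
    m_mediator_snps: int = 12
    n_mediators: int = 0
    n_active_mediators: int = 1
    n_exp: int = 200_000
    n_out: int = 200_000
    n_med: int = 200_000
    theta_direct: float = 0.05
    beta1: float = 0.0
    beta2: float = 0.0
    mu_gamma: float = 0.05
    sigma_gamma: float = 0.01
    fraction_invalid: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    palindrome_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_instruments > self.m_snps:
            raise ValueError("m_instruments must be <= m_snps")
        for name in ("fraction_invalid", "palindrome_fraction", "ld_r2_within"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_exp", "n_out", "n_med", "m_snps", "m_instruments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_active_mediators > max(self.n_mediators, 0):
            self.n_active_mediators = self.n_mediators

    @classmethod
    def mediation_default(cls, **overrides) -> "ScenarioConfig":
        """Reference mediation scenario: one active mediator carrying 40% of
        a total effect of 0.05 (beta1=0.2, beta2=0.1, theta_direct=0.03)."""
        base = dict(
            n_mediators=1, n_active_mediators=1,
            beta1=0.2, beta2=0.1, theta_direct=0.03,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def theta_total(self) -> float:
        """Total causal effect: direct plus all mediated paths."""
        mediated = self.beta1 * self.beta2 * self.n_active_mediators
        return self.theta_direct + mediated


@dataclass
class ScenarioTruth:
    """Ground-truth parameters of a simulated scenario.

    Enables parameter-recovery tests: ``theta_total`` is the probability
    limit of IVW on the valid instruments, and ``proportion_mediated[i]`` the
    target of the two-step mediation estimate for mediator *i*.
    """

    gamma: np.ndarray
    alpha: np.ndarray
    delta: list[np.ndarray]
    theta_direct: float
    beta1: list[float]
    beta2: list[float]
    theta_total: float
    proportion_mediated: list[float]
    instrument_snps: list[str]
    invalid_snps: list[str]
    xi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    outcome_instrument_snps: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_direct": self.theta_direct,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "theta_total": self.theta_total,
            "proportion_mediated": self.proportion_mediated,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "delta": [d.tolist() for d in self.delta],
            "instrument_snps": self.instrument_snps,
            "invalid_snps": self.invalid_snps,
            "xi": self.xi.tolist(),
            "outcome_instrument_snps": self.outcome_instrument_snps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedStudy:
    exposure: GwasSummary
    outcome: GwasSummary
    mediators: list[GwasSummary]
    ld: LdMatrix
    truth: ScenarioTruth


def _standardized_se(n: float, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def binary_outcome_se(eaf: float, n_case: int, n_ctrl: int) -> float:
    """Approximate log-odds SE for a case/control GWAS.

    Uses the effective sample size ``n_case * n_ctrl / (n_case + n_ctrl)`` in
    the standardized-trait formula.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf must lie in (0,1), got {eaf}")
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("case/control counts must be positive")
    n_eff = n_case * n_ctrl / (n_case + n_ctrl)
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, _TINY_P)


def _assemble(label, snp, chrom, pos, ea, oa, eaf, true_beta, n, rng):
    se = _standardized_se(n, eaf)
    beta = true_beta + rng.normal(0.0, se)
    df = pd.DataFrame(
        {
            "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
            "EAF": eaf, "BETA": beta, "SE": se,
            "P": _two_sided_p(beta, se), "N": float(n),
        }
    )
    return GwasSummary(
        trait_label=label, records=validate_gwas_frame(df, label=label)
    )


def simulate_scenario(config: ScenarioConfig) -> SimulatedStudy:
    """Simulate exposure, outcome and mediator GWAS plus LD and ground truth.

    The exposure and outcome tables cover all ``m_snps`` exposure-side SNPs;
    the outcome additionally covers every mediator's instrument SNPs.  Each
    mediator table covers the exposure SNPs (through which the exposure acts
    on it) plus its own instrument SNPs.  Mediators are mutually independent
    given the exposure.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps

    # --- exposure-side SNP annotation -----------------------------------
    snp = np.array([f"rs{j + 1}" for j in range(m)])
    block_of = np.arange(m) // config.ld_block_size
    within = np.arange(m) % config.ld_block_size
    chrom = (block_of % 22 + 1).astype(str)
    pos = 1_000_000 + (block_of // 22) * 2_000_000 + within * 10_000

    n_pal = int(round(config.palindrome_fraction * m))
    pal_idx = rng.choice(m, size=n_pal, replace=False)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if is_pal[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    eaf = rng.uniform(0.05, 0.95, size=m)

    # --- true effects ----------------------------------------------------
    gamma = np.zeros(m)
    inst = np.arange(config.m_instruments)
    lead = within[inst] == 0
    raw = rng.normal(config.mu_gamma, config.sigma_gamma,
                     size=int(lead.sum()))
    block_signal_by_block: dict[int, float] = {}
    for b, g in zip(block_of[inst][lead], raw):
        block_signal_by_block[b] = g
    for j in inst:
        g = block_signal_by_block[block_of[j]]
        gamma[j] = g if within[j] == 0 else g * np.sqrt(config.ld_r2_within)

    alpha = np.zeros(m)
    n_invalid = int(round(config.fraction_invalid * config.m_instruments))
    invalid = rng.choice(inst, size=n_invalid, replace=False)
    alpha[invalid] = rng.normal(config.mu_alpha, config.sigma_alpha,
                                size=n_invalid)

    n_med = config.n_mediators
    beta1 = [config.beta1 if i < config.n_active_mediators else 0.0
             for i in range(n_med)]
    beta2 = [config.beta2 if i < config.n_active_mediators else 0.0
             for i in range(n_med)]
    delta = [rng.normal(config.mu_gamma, config.sigma_gamma,
                        size=config.m_mediator_snps) for _ in range(n_med)]

    theta_total = config.theta_direct + sum(
        b1 * b2 for b1, b2 in zip(beta1, beta2)
    )
    pm_true = [b1 * b2 / theta_total if theta_total != 0 else np.nan
               for b1, b2 in zip(beta1, beta2)]

    # --- outcome-specific genetic architecture ---------------------------
    # SNPs acting on the outcome only: null for the exposure (there is no
    # outcome -> exposure path), they are what reverse MR instruments.
    m_o = config.m_outcome_snps
    out_snp = np.array([f"rs_o{j + 1}" for j in range(m_o)], dtype=object)
    out_chrom = np.array([str(j % 22 + 1) for j in range(m_o)], dtype=object)
    out_pos = np.array([200_000_000 + (j // 22) * 2_000_000
                        for j in range(m_o)])
    out_pairs = [
        _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        for _ in range(m_o)
    ]
    out_ea = np.array([p[0] for p in out_pairs], dtype=object)
    out_oa = np.array([p[1] for p in out_pairs], dtype=object)
    out_eaf = rng.uniform(0.05, 0.95, size=m_o)
    xi = rng.normal(config.mu_gamma, config.sigma_gamma, size=m_o)

    # --- exposure GWAS (exposure SNPs + null rows for outcome SNPs) -----
    exposure = _assemble(
        "exposure",
        np.concatenate([snp, out_snp]),
        np.concatenate([chrom, out_chrom]),
        np.concatenate([pos, out_pos]),
        np.concatenate([ea, out_ea]),
        np.concatenate([oa, out_oa]),
        np.concatenate([eaf, out_eaf]),
        np.concatenate([gamma, np.zeros(m_o)]),
        config.n_exp, rng,
    )

    # --- mediator SNP annotation ----------------------------------------
    med_snp, med_chrom, med_pos, med_ea, med_oa, med_eaf = [], [], [], [], [], []
    for i in range(n_med):
        for j in range(config.m_mediator_snps):
            k = i * config.m_mediator_snps + j
            med_snp.append(f"rs_m{i}_{j}")
            med_chrom.append(str(k % 22 + 1))
            med_pos.append(100_000_000 + (k // 22) * 2_000_000)
        pairs = [
            _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
            for _ in range(config.m_mediator_snps)
        ]
        med_ea.extend(p[0] for p in pairs)
        med_oa.extend(p[1] for p in pairs)
        med_eaf.extend(rng.uniform(0.05, 0.95, size=config.m_mediator_snps))
    med_snp = np.array(med_snp, dtype=object)
    med_eaf = np.array(med_eaf, dtype=float)

    # --- outcome GWAS (exposure SNPs + every mediator's SNPs) -----------
    out_true_exp = gamma * theta_total + alpha
    out_true_med = np.concatenate(
        [delta[i] * beta2[i] for i in range(n_med)]
    ) if n_med else np.array([])
    outcome = _assemble(
        "outcome",
        np.concatenate([snp, out_snp, med_snp]),
        np.concatenate([chrom, out_chrom, np.array(med_chrom, dtype=object)]),
        np.concatenate([pos, out_pos, np.array(med_pos)]),
        np.concatenate([ea, out_ea, np.array(med_ea, dtype=object)]),
        np.concatenate([oa, out_oa, np.array(med_oa, dtype=object)]),
        np.concatenate([eaf, out_eaf, med_eaf]),
        np.concatenate([out_true_exp, xi, out_true_med]),
        config.n_out, rng,
    )

    # --- mediator GWAS ---------------------------------------------------
    mediators = []
    for i in range(n_med):
        lo = i * config.m_mediator_snps
        hi = lo + config.m_mediator_snps
        mediators.append(
            _assemble(
                f"mediator_{i:03d}",
                np.concatenate([snp, med_snp[lo:hi]]),
                np.concatenate([chrom, np.array(med_chrom[lo:hi], dtype=object)]),
                np.concatenate([pos, np.array(med_pos[lo:hi])]),
                np.concatenate([ea, np.array(med_ea[lo:hi], dtype=object)]),
                np.concatenate([oa, np.array(med_oa[lo:hi], dtype=object)]),
                np.concatenate([eaf, med_eaf[lo:hi]]),
                np.concatenate([gamma * beta1[i], delta[i]]),
                config.n_med, rng,
            )
        )

    # --- LD matrix: within-block pairs only ------------------------------
    ld = LdMatrix()
    if config.ld_block_size > 1 and config.ld_r2_within > 0:
        for b in np.unique(block_of):
            members = snp[block_of == b]
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    ld.set_r2(members[a_i], members[b_i],
                              config.ld_r2_within)

    truth = ScenarioTruth(
        gamma=gamma, alpha=alpha, delta=delta,
        theta_direct=config.theta_direct,
        beta1=beta1, beta2=beta2, theta_total=theta_total,
        proportion_mediated=pm_true,
        instrument_snps=[str(s) for s in snp[inst]],
        invalid_snps=[str(s) for s in snp[np.sort(invalid)]],
        xi=xi,
        outcome_instrument_snps=[str(s) for s in out_snp],
    )
    return SimulatedStudy(exposure, outcome, mediators, ld, truth)


def simulate_instrument_set(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[InstrumentSet, ScenarioTruth]:
    """Directly simulate a harmonized instrument set (estimator benchmark path).

    Draws the exposure and outcome associations of the ``m_instruments``
    instrument SNPs under the same model as :func:`simulate_scenario` but
    skips the file-level tables, allele bookkeeping and re-selection — the
    configuration it reflects is "these k instruments were selected and
    harmonized".  Used for Monte-Carlo calibration of the estimators.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = config.m_instruments
    gamma = rng.normal(config.mu_gamma, config.sigma_gamma, size=k)
    eaf = rng.uniform(0.05, 0.95, size=k)
    se_exp = _standardized_se(config.n_exp, eaf)
    se_out = _standardized_se(config.n_out, eaf)
    alpha = np.zeros(k)
    n_invalid = int(round(config.fraction_invalid * k))
    invalid = rng.choice(k, size=n_invalid, replace=False)
    alpha[invalid] = rng.normal(config.mu_alpha, config.sigma_alpha,
                                size=n_invalid)
    beta_exp = gamma + rng.normal(0.0, se_exp)
    beta_out = gamma * config.theta_total + alpha + rng.normal(0.0, se_out)
    snp = [f"rs{j + 1}" for j in range(k)]
    table = pd.DataFrame(
        {
            "SNP": snp,
            "BETA_EXP": beta_exp, "SE_EXP": se_exp,
            "BETA_OUT": beta_out, "SE_OUT": se_out,
            "EAF_EXP": eaf, "EAF_OUT": eaf,
            "ACTION": "aligned",
        },
        columns=HARMONIZED_COLUMNS,
    )
    iset = InstrumentSet(
        exposure_label="exposure", outcome_label="outcome", table=table
    )
    truth = ScenarioTruth(
        gamma=gamma, alpha=alpha, delta=[],
        theta_direct=config.theta_direct,
        beta1=[], beta2=[], theta_total=config.theta_total,
        proportion_mediated=[],
        instrument_snps=snp,
        invalid_snps=[snp[j] for j in np.sort(invalid)],
    )
    return iset, truth


def write_scenario(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study as summary-TSV / LD-TSV / truth-JSON files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld.tsv",
        "truth": out_dir / "truth.json",
    }
    write_gwas_summary(study.exposure, paths["exposure"])
    write_gwas_summary(study.outcome, paths["outcome"])
    write_ld_matrix(study.ld, paths["ld"])
    study.truth.to_json(paths["truth"])
    for i, med in enumerate(study.mediators):
        p = out_dir / f"mediator_{i:03d}.tsv"
        write_gwas_summary(med, p)
        paths[med.trait_label] = p
    return paths
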