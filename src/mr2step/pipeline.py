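"""End-to-end orchestration: forward MR, reverse MR, sensitivity, mediation.

The pipeline reproduces the shape of a bidirectional two-sample MR study:
for every exposure dataset it selects instruments, harmonizes them against
the outcome, runs the six-estimator panel plus the sensitivity suite, then
swaps roles for reverse MR, screens a mediator panel with two-step MR, and
scans instruments against a local confounder catalogue.  One global seed
fans out to per-stage seeds by fixed offsets so each stage is independently
reproducible; identical configuration gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import estimate_all, ivw
from .harmonize import harmonize
from .instruments import (
    confounder_scan,
    read_confounder_catalogue,
    select_instruments,
    set_f_statistic,
)
from .mediation import mediation_results_frame, screen_mediators
from .sensitivity import cochran_q, egger_intercept_test, leave_one_out, mr_presso
from .summary_io import GwasSummary, LdMatrix, read_gwas_summary, read_ld_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisThresholds", "PipelineConfig", "ConfigError", "StudyReport",
    "analyze_pair", "run_forward", "run_reverse", "run_full", "write_report",
]

# fixed per-stage seed offsets (global seed + offset, kept below 2**31)
SEED_OFFSET_MR = 101
SEED_OFFSET_PRESSO = 211
SEED_OFFSET_MEDIATION = 307
SEED_OFFSET_PER_EXPOSURE = 1009


class ConfigError(ValueError):
    """The pipeline configuration is invalid or references missing files."""


@dataclass
class AnalysisThresholds:
    """Analysis parameters; defaults follow standard two-sample MR practice
    (5e-8 primary / 5e-6 relaxed significance, r² < 0.001 within 10,000 kb
    clumping, F >= 10, palindrome MAF cutoff 0.42, alpha 0.05)."""

    p_threshold: float = 5e-8
    relaxed_threshold: float = 5e-6
    relaxed_min_snps: int = 4
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    maf_ambiguity: float = 0.42
    alpha: float = 0.05
    presso_nsim: int = 1000
    n_boot: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_threshold", "relaxed_threshold", "clump_r2",
                     "maf_ambiguity", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0,1), got {v}")
        if self.clump_kb <= 0 or self.f_min < 0:
            raise ConfigError("clump_kb must be > 0 and f_min >= 0")


@dataclass
class PipelineConfig:
    """File-level pipeline configuration (one JSON document)."""

    exposures: list[str]
    outcome: str
    ld: str
    panel: list[str] = field(default_factory=list)
    confounder_catalogue: str | None = None
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    seed: int = 0
    out_dir: str = "mr2step_report"
    default_n: float | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        thr = AnalysisThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def validate_paths(self) -> None:
        paths = [*self.exposures, self.outcome, self.ld, *self.panel]
        if self.confounder_catalogue:
            paths.append(self.confounder_catalogue)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(
                "missing input file(s): " + ", ".join(str(m) for m in missing)
            )


@dataclass
class StudyReport:
    """All result tables of one pipeline run plus run metadata."""

    estimates: pd.DataFrame
    sensitivity: pd.DataFrame
    loo: pd.DataFrame
    attrition: pd.DataFrame
    reverse_estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    reverse_sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediation: pd.DataFrame = field(default_factory=pd.DataFrame)
    confounder_flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)


def _attrition_frame(exposure_label, selected, attrition_counts, iset):
    """Per-SNP drop ledger: each dropped SNP appears once with one reason."""
    rows = []
    for r in iset.dropped.itertuples(index=False):
        rows.append({"EXPOSURE": exposure_label, "SNP": r.SNP,
                     "STAGE": "harmonization", "REASON": r.REASON})
    frame = pd.DataFrame(rows, columns=["EXPOSURE", "SNP", "STAGE", "REASON"])
    counts = pd.DataFrame([
        {"EXPOSURE": exposure_label, **attrition_counts,
         "n_harmonized": iset.k}
    ])
    return frame, counts


def analyze_pair(
    exposure: GwasSummary,
    outcome: GwasSummary,
    ld: LdMatrix,
    thresholds: AnalysisThresholds | None = None,
    seed: int = 0,
    *,
    direction: str = "forward",
    run_presso: bool = True,
) -> dict:
    """Select -> harmonize -> estimate -> sensitivity for one exposure.

    Returns a dict with the estimate table, the sensitivity row, the
    leave-one-out table, the harmonized set and attrition accounting.
    """
    thr = thresholds or AnalysisThresholds()
    selected, att = select_instruments(
        exposure, ld,
        p_threshold=thr.p_threshold,
        relaxed_threshold=thr.relaxed_threshold,
        relaxed_min_snps=thr.relaxed_min_snps,
        clump_r2=thr.clump_r2, clump_kb=thr.clump_kb, f_min=thr.f_min,
    )
    if len(selected) == 0:
        raise ValueError(f"no instruments selected for {exposure.trait_label}")
    iset = harmonize(exposure, outcome, selected["SNP"].tolist(),
                     maf_ambiguity=thr.maf_ambiguity)
    est = estimate_all(iset, seed=seed + SEED_OFFSET_MR, n_boot=thr.n_boot)
    est.insert(0, "EXPOSURE", exposure.trait_label)
    est.insert(1, "OUTCOME", outcome.trait_label)
    est.insert(2, "DIRECTION", direction)

    sens_row = {
        "EXPOSURE": exposure.trait_label, "OUTCOME": outcome.trait_label,
        "DIRECTION": direction,
    }
    loo = pd.DataFrame()
    if iset.k >= 3:
        q_egger = cochran_q(iset, "egger")
        q_ivw = cochran_q(iset, "ivw")
        intercept = egger_intercept_test(iset)
        sens_row.update({
            "EGGER_Q": q_egger.Q, "EGGER_Q_P": q_egger.pval,
            "IVW_Q": q_ivw.Q, "IVW_Q_P": q_ivw.pval,
            "EGGER_INTERCEPT": intercept.beta, "INTERCEPT_P": intercept.pval,
            "MRE_JUSTIFIED": q_ivw.pval < thr.alpha,
        })
        loo = leave_one_out(iset)
        loo.insert(0, "EXPOSURE", exposure.trait_label)
    if run_presso and iset.k >= 4:
        presso = mr_presso(iset, n_sim=thr.presso_nsim,
                           seed=seed + SEED_OFFSET_PRESSO,
                           outlier_alpha=thr.alpha)
        sens_row.update({
            "PRESSO_GLOBAL_P": presso.global_pval,
            "PRESSO_OUTLIERS": ";".join(presso.outliers),
        })
    att_frame, att_counts = _attrition_frame(
        exposure.trait_label, selected, att, iset
    )
    sens_row["SET_F"] = set_f_statistic(selected)
    sens_row["MEDIAN_F"] = float(selected["F_STAT"].median())
    return {
        "estimates": est,
        "sensitivity": pd.DataFrame([sens_row]),
        "loo": loo,
        "instrument_set": iset,
        "selected": selected,
        "attrition": att_frame,
        "attrition_counts": att_counts,
    }


def _error_block(label: str, outcome_label: str, direction: str, exc: Exception):
    est = pd.DataFrame([{
        "EXPOSURE": label, "OUTCOME": outcome_label, "DIRECTION": direction,
        "METHOD": "(error)", "NSNP": 0, "BETA": np.nan, "SE": np.nan,
        "OR": np.nan, "OR_L95": np.nan, "OR_U95": np.nan, "PVAL": np.nan,
        "STATUS": f"error: {exc}",
    }])
    return {"estimates": est, "sensitivity": pd.DataFrame(),
            "loo": pd.DataFrame(), "instrument_set": None,
            "selected": pd.DataFrame(), "attrition": pd.DataFrame(),
            "attrition_counts": pd.DataFrame()}


def _fan_out(config: PipelineConfig, datasets, outcome, ld, direction):
    blocks = []
    for i, exposure in enumerate(datasets):
        seed_i = config.seed + i * SEED_OFFSET_PER_EXPOSURE
        try:
            blocks.append(analyze_pair(
                exposure, outcome, ld, config.thresholds, seed_i,
                direction=direction,
            ))
        except Exception as exc:  # isolate per-exposure failures
            logger.error("%s analysis failed for %s: %s", direction,
                         exposure.trait_label, exc)
            blocks.append(_error_block(exposure.trait_label,
                                       outcome.trait_label, direction, exc))
    return blocks


def _concat(blocks, key):
    frames = [b[key] for b in blocks if len(b[key])]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _load_inputs(config: PipelineConfig):
    config.validate_paths()
    exposures = [read_gwas_summary(p, default_n=config.default_n)
                 for p in config.exposures]
    outcome = read_gwas_summary(config.outcome, default_n=config.default_n)
    ld = read_ld_matrix(config.ld)
    panel = [read_gwas_summary(p, default_n=config.default_n)
             for p in config.panel]
    return exposures, outcome, ld, panel


def run_forward(config: PipelineConfig) -> dict:
    """Forward MR for every exposure dataset against the outcome."""
    exposures, outcome, ld, _ = _load_inputs(config)
    blocks = _fan_out(config, exposures, outcome, ld, "forward")
    return {
        "estimates": _concat(blocks, "estimates"),
        "sensitivity": _concat(blocks, "sensitivity"),
        "loo": _concat(blocks, "loo"),
        "attrition": _concat(blocks, "attrition"),
        "attrition_counts": _concat(blocks, "attrition_counts"),
        "blocks": blocks,
    }


def run_reverse(config: PipelineConfig) -> dict:
    """Reverse MR: the outcome re-selected as exposure against each original
    exposure, to exclude reverse causation."""
    exposures, outcome, ld, _ = _load_inputs(config)
    blocks = []
    for exposure in exposures:
        blocks.extend(_fan_out(config, [outcome], exposure, ld, "reverse"))
    return {
        "estimates": _concat(blocks, "estimates"),
        "sensitivity": _concat(blocks, "sensitivity"),
        "blocks": blocks,
    }


def run_full(config: PipelineConfig) -> StudyReport:
    """Forward + reverse MR, mediation screen and confounder scan."""
    exposures, outcome, ld, panel = _load_inputs(config)
    fwd_blocks = _fan_out(config, exposures, outcome, ld, "forward")
    rev_blocks = []
    for exposure in exposures:
        rev_blocks.extend(_fan_out(config, [outcome], exposure, ld, "reverse"))

    mediation_df = pd.DataFrame()
    if panel:
        thr = config.thresholds
        results = screen_mediators(
            exposures[0], outcome, panel, ld,
            p_threshold=thr.p_threshold,
            relaxed_threshold=thr.relaxed_threshold,
            relaxed_min_snps=thr.relaxed_min_snps,
            clump_r2=thr.clump_r2, clump_kb=thr.clump_kb,
            f_min=thr.f_min, maf_ambiguity=thr.maf_ambiguity,
            alpha=thr.alpha,
        )
        mediation_df = mediation_results_frame(results)

    confounder_df = pd.DataFrame()
    if config.confounder_catalogue:
        catalogue = read_confounder_catalogue(config.confounder_catalogue)
        flag_frames = []
        for b in fwd_blocks:
            if len(b["selected"]):
                flags = confounder_scan(b["selected"], catalogue, ld)
                flag_frames.append(flags)
        if flag_frames:
            confounder_df = pd.concat(flag_frames, ignore_index=True)

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "thresholds"},
            "thresholds": dataclasses.asdict(config.thresholds),
        },
    }
    return StudyReport(
        estimates=_concat(fwd_blocks, "estimates"),
        sensitivity=_concat(fwd_blocks, "sensitivity"),
        loo=_concat(fwd_blocks, "loo"),
        attrition=pd.concat(
            [_concat(fwd_blocks, "attrition_counts"),
             ], ignore_index=True
        ),
        reverse_estimates=_concat(rev_blocks, "estimates"),
        reverse_sensitivity=_concat(rev_blocks, "sensitivity"),
        mediation=mediation_df,
        confounder_flags=confounder_df,
        metadata=metadata,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_report(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write machine-precision TSVs, 3-decimal display tables and a JSON
    summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "estimates": report.estimates,
        "sensitivity": report.sensitivity,
        "leave_one_out": report.loo,
        "attrition": report.attrition,
        "reverse_estimates": report.reverse_estimates,
        "reverse_sensitivity": report.reverse_sensitivity,
        "mediation": report.mediation,
        "confounder_flags": report.confounder_flags,
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        _write_tsv(df if len(df) else pd.DataFrame(), p)
        paths[name] = p
        if len(df):
            disp = df.copy()
            num = disp.select_dtypes(include=[np.number]).columns
            disp[num] = disp[num].round(3)
            dp = out_dir / f"display_{name}.tsv"
            disp.to_csv(dp, sep="\t", index=False)
            paths[f"display_{name}"] = dp
    summary = out_dir / "summary.json"
    with open(summary, "w") as fh:
        json.dump(report.metadata, fh, indent=1, default=str)
    paths["summary"] = summary
    return paths
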