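"""Reading, validating and writing GWAS summary statistics and LD tables.

Two plain-text dialects are used throughout the package:

* **GWAS summary TSV** — header row, tab separated, canonical columns
  ``SNP CHR POS EA OA EAF BETA SE P N``.  ``column_map`` on read lets callers
  alias arbitrary headers onto the canonical names.
* **LD TSV** — columns ``SNP_A SNP_B R2`` holding pairwise r² values; pairs
  absent from the file are taken to be in linkage equilibrium (r² = 0).

Only single-nucleotide biallelic variants are handled; rows carrying indels or
out-of-range numerics are dropped at parse with a logged count.  Records whose
reported p-value disagrees with the p implied by ``|BETA/SE|`` (two-sided
normal) are *flagged*, never dropped: published summary files routinely carry
heavily rounded p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical GWAS summary columns, in on-disk order
GWAS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
#: columns that must be present (N may instead come from ``default_n``)
MANDATORY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]
_NUMERIC_COLUMNS = ["POS", "EAF", "BETA", "SE", "P", "N"]

LD_COLUMNS = ["SNP_A", "SNP_B", "R2"]

#: relative tolerance on the -log10 scale for the p vs beta/se consistency flag
PVAL_LOG10_RTOL = 0.5


class SummaryFormatError(ValueError):
    """A summary-statistics file violates the expected tabular dialect."""


def implied_log10_pval(beta, se):
    """-log10 of the two-sided normal p implied by ``|beta/se|``.

    Computed through ``norm.logsf`` so genome-wide z-scores do not underflow.
    """
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return -(np.log(2.0) + stats.norm.logsf(z)) / np.log(10.0)


def pval_consistent(beta, se, pval, rtol: float = PVAL_LOG10_RTOL):
    """True where the reported p matches the beta/se-implied p.

    Agreement is judged on the -log10 scale with relative tolerance ``rtol``:
    ``|l_implied - l_reported| <= rtol * max(l_implied, l_reported)``.
    """
    l_imp = implied_log10_pval(beta, se)
    l_obs = -np.log10(np.asarray(pval, dtype=float))
    return np.abs(l_imp - l_obs) <= rtol * np.maximum(l_imp, l_obs)


@dataclass
class GwasSummary:
    """One GWAS, as a validated table of per-SNP associations.

    ``records`` carries the canonical columns plus a boolean ``CONSISTENT``
    flag column.  Effect sizes are per effect-allele: log-odds for binary
    traits, SD units for standardized quantitative traits.
    """

    trait_label: str
    records: pd.DataFrame
    trait_type: str = "quantitative"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if len(self.records) == 0:
            raise SummaryFormatError("empty dataset")
        dup = self.records["SNP"][self.records["SNP"].duplicated()]
        if len(dup):
            raise SummaryFormatError(
                "duplicate snp_id: " + ", ".join(sorted(set(dup)))
            )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["SNP"].tolist()

    def subset(self, snp_ids: Iterable[str]) -> "GwasSummary":
        keep = self.records[self.records["SNP"].isin(set(snp_ids))]
        return GwasSummary(
            trait_label=self.trait_label,
            records=keep.reset_index(drop=True),
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


def validate_gwas_frame(
    df: pd.DataFrame, *, default_n: float | None = None, label: str = ""
) -> pd.DataFrame:
    """Coerce, range-check and flag a raw summary frame.

    Rows with non-parseable or out-of-range numerics, or non-SNP alleles, are
    dropped (count logged).  Numeric values of surviving rows are never
    altered; the only derived column is the ``CONSISTENT`` flag.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryFormatError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )
    df = df.copy()
    if "N" not in df.columns:
        if default_n is None:
            raise SummaryFormatError("missing mandatory column(s): N")
        df["N"] = default_n

    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.upper()
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if default_n is not None:
        df["N"] = df["N"].fillna(default_n)

    n_before = len(df)
    ok = np.ones(n_before, dtype=bool)
    ok &= df[_NUMERIC_COLUMNS].notna().all(axis=1).to_numpy()
    ok &= df["EA"].isin(VALID_BASES).to_numpy()
    ok &= df["OA"].isin(VALID_BASES).to_numpy()
    ok &= (df["EA"] != df["OA"]).to_numpy()
    with np.errstate(invalid="ignore"):
        ok &= (df["SE"].to_numpy() > 0)
        ok &= (df["EAF"].to_numpy() > 0) & (df["EAF"].to_numpy() < 1)
        ok &= (df["P"].to_numpy() > 0) & (df["P"].to_numpy() <= 1)
        ok &= df["N"].to_numpy() > 0
        ok &= df["POS"].to_numpy() > 0
    dropped = int(n_before - ok.sum())
    if dropped:
        logger.warning(
            "%s: dropped %d/%d malformed row(s) at parse", label or "gwas",
            dropped, n_before,
        )
    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise SummaryFormatError("empty dataset")
    df["POS"] = df["POS"].astype(np.int64)
    df["N"] = df["N"].astype(float)
    df["CONSISTENT"] = pval_consistent(df["BETA"], df["SE"], df["P"])
    return df[GWAS_COLUMNS + ["CONSISTENT"]]


def read_gwas_summary(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_label: str | None = None,
    default_n: float | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> GwasSummary:
    """Read a GWAS summary TSV into a validated :class:`GwasSummary`.

    Parameters
    ----------
    column_map
        Mapping from file header names to canonical names, for files using
        non-canonical headers (e.g. ``{"rsid": "SNP", "pvalue": "P"}``).
    default_n
        Per-dataset sample size used for rows (or files) lacking ``N``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    records = validate_gwas_frame(df, default_n=default_n, label=path.name)
    return GwasSummary(
        trait_label=trait_label or path.stem,
        records=records,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_gwas_summary(gwas: GwasSummary, path: str | Path) -> None:
    """Write the canonical columns to TSV at full double precision."""
    if len(gwas.records) == 0:
        raise SummaryFormatError("empty dataset")
    gwas.records[GWAS_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


class LdMatrix:
    """Sparse symmetric pairwise-r² store over SNP identifiers.

    The diagonal is implicitly 1; pairs never entered are implicitly 0
    (linkage equilibrium).  All stored values must lie in [0, 1].
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        self._ids: dict[str, None] = {}

    @property
    def snp_ids(self) -> list[str]:
        return list(self._ids)

    def __len__(self) -> int:
        return len(self._ids)

    def set_r2(self, snp_a: str, snp_b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of range [0,1]: {r2} ({snp_a},{snp_b})")
        if snp_a == snp_b:
            if r2 != 1.0:
                raise ValueError(f"diagonal r2 must be 1, got {r2} ({snp_a})")
            self._ids.setdefault(snp_a, None)
            return
        self._ids.setdefault(snp_a, None)
        self._ids.setdefault(snp_b, None)
        self._r2[(snp_a, snp_b)] = r2
        self._r2[(snp_b, snp_a)] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get((snp_a, snp_b), 0.0)

    def has_pair(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or (snp_a, snp_b) in self._r2

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdMatrix":
        ld = cls()
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
            ld.set_r2(str(a), str(b), float(r2))
        return ld

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (a, b, r2) for (a, b), r2 in self._r2.items() if a < b
        )
        return pd.DataFrame(rows, columns=LD_COLUMNS)


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read an LD TSV (``SNP_A SNP_B R2``); an empty file is all-equilibrium."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
    except pd.errors.EmptyDataError:
        return LdMatrix()
    if len(df) == 0:
        return LdMatrix()
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryFormatError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )
    return LdMatrix.from_frame(df)


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    ld.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
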