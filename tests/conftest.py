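import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mr2step.harmonize import HARMONIZED_COLUMNS, InstrumentSet
from mr2step.summary_io import GwasSummary, validate_gwas_frame
from mr2step.synthetic import ScenarioConfig, simulate_instrument_set


def make_instrument_set(bx, sx, by, sy, snp=None) -> InstrumentSet:
    """Build a harmonized instrument set directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    k = bx.size
    table = pd.DataFrame(
        {
            "SNP": snp if snp is not None else [f"rs{i + 1}" for i in range(k)],
            "BETA_EXP": bx,
            "SE_EXP": np.broadcast_to(np.asarray(sx, float), (k,)),
            "BETA_OUT": np.asarray(by, dtype=float),
            "SE_OUT": np.broadcast_to(np.asarray(sy, float), (k,)),
            "EAF_EXP": 0.3,
            "EAF_OUT": 0.3,
            "ACTION": "aligned",
        },
        columns=HARMONIZED_COLUMNS,
    )
    return InstrumentSet("exposure", "outcome", table)


def gwas_from_rows(rows, label="trait", default_n=10_000.0, **kwargs) -> GwasSummary:
    """GwasSummary from partial row dicts; unspecified fields get defaults
    and P defaults to the value implied by BETA/SE."""
    full = []
    for i, row in enumerate(rows):
        r = {
            "SNP": f"rs{i + 1}", "CHR": "1", "POS": 1000 + i * 1000,
            "EA": "A", "OA": "G", "EAF": 0.3, "BETA": 0.1, "SE": 0.02,
            "N": default_n,
        }
        r.update(row)
        if "P" not in r:
            r["P"] = float(2 * stats.norm.sf(abs(r["BETA"] / r["SE"])))
        full.append(r)
    df = validate_gwas_frame(pd.DataFrame(full), default_n=default_n)
    return GwasSummary(trait_label=label, records=df, **kwargs)


@pytest.fixture
def default_iset():
    """A 60-instrument harmonized set under the reference scenario."""
    iset, truth = simulate_instrument_set(ScenarioConfig(), seed=42)
    return iset, truth
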