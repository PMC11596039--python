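"""Instrument selection: significance filter, clumping, strength filters."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mr2step.instruments import (
    clump,
    confounder_scan,
    f_statistic,
    select_instruments,
    set_f_statistic,
    significance_filter,
    variance_explained,
    weak_filter,
)
from mr2step.summary_io import LdMatrix

from conftest import gwas_from_rows


@pytest.fixture
def three_pvals():
    return gwas_from_rows([
        {"SNP": "rs1", "P": 1e-9},
        {"SNP": "rs2", "P": 1e-7, "POS": 2_000_000},
        {"SNP": "rs3", "P": 1e-5, "POS": 4_000_000},
    ])


class TestSignificanceFilter:
    def test_genome_wide_threshold(self, three_pvals):
        assert significance_filter(three_pvals, 5e-8)["SNP"].tolist() == ["rs1"]

    def test_relaxed_threshold(self, three_pvals):
        kept = significance_filter(three_pvals, 5e-6)
        assert kept["SNP"].tolist() == ["rs1", "rs2"]

    def test_empty_survivors(self, three_pvals):
        assert len(significance_filter(three_pvals, 1e-12)) == 0

    def test_sorted_ascending_p(self, three_pvals):
        kept = significance_filter(three_pvals, 0.5)
        assert kept["P"].is_monotonic_increasing


def _ld(pairs):
    ld = LdMatrix()
    for a, b, r2 in pairs:
        ld.set_r2(a, b, r2)
    return ld


def _candidates(rows):
    return gwas_from_rows(rows).records


class TestClump:
    def test_correlated_neighbors_pruned(self):
        cand = _candidates([
            {"SNP": "rs1", "POS": 1000, "P": 1e-10},
            {"SNP": "rs2", "POS": 2000, "P": 1e-9},
        ])
        kept = clump(cand, _ld([("rs1", "rs2", 0.5)]), 0.001, 10_000)
        assert kept["SNP"].tolist() == ["rs1"]

    def test_sub_threshold_ld_kept(self):
        cand = _candidates([
            {"SNP": "rs1", "POS": 1000, "P": 1e-10},
            {"SNP": "rs2", "POS": 2000, "P": 1e-9},
        ])
        kept = clump(cand, _ld([("rs1", "rs2", 0.0005)]), 0.001, 10_000)
        assert kept["SNP"].tolist() == ["rs1", "rs2"]

    def test_outside_window_kept(self):
        cand = _candidates([
            {"SNP": "rs1", "POS": 1_000, "P": 1e-10},
            {"SNP": "rs2", "POS": 20_001_000, "P": 1e-9},
        ])
        kept = clump(cand, _ld([("rs1", "rs2", 0.9)]), 0.001, 10_000)
        assert len(kept) == 2

    def test_missing_pair_treated_as_zero(self):
        cand = _candidates([
            {"SNP": "rs1", "POS": 1000, "P": 1e-10},
            {"SNP": "rs2", "POS": 2000, "P": 1e-9},
        ])
        kept = clump(cand, LdMatrix(), 0.001, 10_000)
        assert len(kept) == 2

    def test_input_order_irrelevant(self):
        cand = _candidates([
            {"SNP": "rs1", "POS": 1000, "P": 1e-8},
            {"SNP": "rs2", "POS": 2000, "P": 1e-10},
            {"SNP": "rs3", "POS": 3000, "P": 1e-9},
        ])
        ld = _ld([("rs1", "rs2", 0.9), ("rs2", "rs3", 0.9)])
        a = clump(cand, ld, 0.001, 10_000)
        b = clump(cand.iloc[::-1].reset_index(drop=True), ld, 0.001, 10_000)
        assert a["SNP"].tolist() == b["SNP"].tolist() == ["rs2"]

    def test_idempotent(self):
        cand = _candidates([
            {"SNP": f"rs{i}", "POS": 1000 * i, "P": 10.0 ** -(8 + i)}
            for i in range(1, 7)
        ])
        ld = _ld([("rs1", "rs2", 0.9), ("rs3", "rs4", 0.9)])
        once = clump(cand, ld, 0.001, 10_000)
        twice = clump(once, ld, 0.001, 10_000)
        pd.testing.assert_frame_equal(once, twice)


def _clump_oracle(df, ld, r2_max, window_kb):
    """Independent greedy reference: literal restatement of the rule."""
    remaining = df.sort_values(["P", "CHR", "POS"]).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["SNP"])
        remaining = [
            r for r in remaining
            if not (
                r["CHR"] == index["CHR"]
                and abs(r["POS"] - index["POS"]) <= window_kb * 1000
                and ld.r2(index["SNP"], r["SNP"]) >= r2_max
            )
        ]
    return kept


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_clump_matches_bruteforce_oracle(data):
    n = data.draw(st.integers(2, 12))
    pvals = data.draw(
        st.lists(st.floats(1e-30, 1e-8), min_size=n, max_size=n, unique=True)
    )
    chroms = data.draw(st.lists(st.sampled_from(["1", "2"]),
                                min_size=n, max_size=n))
    positions = data.draw(
        st.lists(st.integers(1, 30_000_000), min_size=n, max_size=n,
                 unique=True)
    )
    cand = _candidates([
        {"SNP": f"rs{i}", "CHR": chroms[i], "POS": positions[i],
         "P": pvals[i]}
        for i in range(n)
    ])
    ld = LdMatrix()
    for i in range(n):
        for j in range(i + 1, n):
            if data.draw(st.booleans()):
                ld.set_r2(f"rs{i}", f"rs{j}",
                          data.draw(st.floats(0.0, 1.0)))
    kept = clump(cand, ld, 0.001, 10_000)
    assert kept["SNP"].tolist() == _clump_oracle(cand, ld, 0.001, 10_000)


class TestStrength:
    def test_variance_explained_hand_value(self):
        assert variance_explained(0.1, 0.5) == pytest.approx(0.005)

    def test_variance_explained_null_and_symmetry(self):
        assert variance_explained(0.0, 0.3) == 0.0
        assert variance_explained(0.1, 0.2) == pytest.approx(
            variance_explained(0.1, 0.8), rel=1e-12
        )

    def test_variance_explained_range_error(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 1.5)

    def test_f_hand_values(self):
        assert f_statistic(0.01, 10_000, 10) == pytest.approx(10.0899, abs=1e-3)
        assert f_statistic(0.0, 10_000, 1) == 0.0
        # a barely significant SNP falls below the Staiger–Stock bound of 10
        assert f_statistic(0.0005, 10_000, 1) == pytest.approx(5.0015, abs=1e-3)
        assert f_statistic(0.0005, 10_000, 1) < 10

    def test_f_monotonicity(self):
        assert f_statistic(0.02, 10_000, 1) > f_statistic(0.01, 10_000, 1)
        assert f_statistic(0.01, 20_000, 1) > f_statistic(0.01, 10_000, 1)
        assert f_statistic(0.01, 10_000, 2) < f_statistic(0.01, 10_000, 1)

    def test_f_domain_error(self):
        with pytest.raises(ValueError, match="sample size"):
            f_statistic(0.01, 10, 10)

    def test_weak_filter_boundary(self):
        cand = _candidates([{}, {}, {}])
        cand["F_STAT"] = [5.0, 10.0, 45.0]
        kept = weak_filter(cand, f_min=10.0)
        assert len(kept) == 2  # F = 10 retained at the boundary
        assert kept["F_STAT"].tolist() == [10.0, 45.0]

    def test_all_weak_empty(self):
        cand = _candidates([{"BETA": 1e-4, "EAF": 0.5}])
        assert len(weak_filter(cand)) == 0

    def test_set_level_f(self):
        cand = _candidates([{"BETA": 0.1, "EAF": 0.5}] * 1)
        assert set_f_statistic(cand) > 0


class TestConfounderScan:
    catalogue = pd.DataFrame({
        "SNP": ["rs_c1", "rs_c2"],
        "CHR": ["1", "1"],
        "POS": [101_000, 601_000],
        "TRAIT": ["type 2 diabetes", "smoking"],
        "R2": [0.5, 0.9],
    })

    def _cands(self):
        return _candidates([{"SNP": "rs1", "POS": 1_000}])

    def test_nearby_linked_flagged(self):
        flags = confounder_scan(self._cands(), self.catalogue)
        assert flags["TRAIT"].tolist() == ["type 2 diabetes"]

    def test_outside_window_not_flagged(self):
        far = self.catalogue.iloc[[1]]
        assert len(confounder_scan(self._cands(), far)) == 0

    def test_empty_catalogue(self):
        empty = self.catalogue.iloc[:0]
        assert len(confounder_scan(self._cands(), empty)) == 0

    def test_ld_matrix_overrides_catalogue_r2(self):
        ld = _ld([("rs1", "rs_c1", 0.01)])
        flags = confounder_scan(self._cands(), self.catalogue, ld)
        assert len(flags) == 0


class TestSelectInstruments:
    def test_relaxed_policy_engages_for_sparse_traits(self):
        rows = [{"SNP": f"rs{i}", "POS": i * 20_000_000, "P": 1e-7}
                for i in range(1, 6)]
        gwas = gwas_from_rows(rows)
        # make betas strong enough to pass the F filter
        gwas.records["BETA"] = 0.1
        selected, att = select_instruments(gwas, LdMatrix())
        assert att["relaxed"] is True
        assert len(selected) == 5
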