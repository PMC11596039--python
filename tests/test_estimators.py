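"""The six MR estimators against hand-computed and brute-force oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mr2step.estimators import (
    egger,
    estimate_all,
    ivw,
    max_likelihood,
    mode_estimate,
    wald_ratio,
    weighted_median,
)

from conftest import make_instrument_set


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0
        assert est.pval == 1.0

    def test_sign_flip_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.01)
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.1, 0.05, 0.05, 0.01)
        second = wald_ratio(0.1, 0.05, 0.05, 0.01, second_order=True)
        assert second.se > first.se


class TestIvw:
    def test_equal_weight_mean(self):
        iset = make_instrument_set([1.0, 1.0], 0.01, [0.4, 0.6], 1.0)
        assert ivw(iset, "fixed").beta == pytest.approx(0.5)

    def test_weighted_mean_hand_oracle(self):
        # ratios {0.2, 0.5, 0.8} with weights {4, 1, 4} -> 0.5
        bx = np.array([2.0, 1.0, 2.0])
        by = np.array([0.4, 0.5, 1.6])
        iset = make_instrument_set(bx, 0.01, by, 1.0)
        assert ivw(iset, "fixed").beta == pytest.approx(0.5, abs=1e-12)

    def test_mre_floor_on_homogeneous_set(self):
        bx = np.array([1.0, 2.0, 3.0])
        iset = make_instrument_set(bx, 0.01, 0.5 * bx, 0.02)
        fixed, mre = ivw(iset, "fixed"), ivw(iset, "mre")
        assert mre.se == fixed.se  # Q = 0 -> floor active
        assert mre.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_k1_rejected(self):
        iset = make_instrument_set([1.0], 0.01, [0.5], 0.02)
        with pytest.raises(ValueError, match="k >= 2"):
            ivw(iset)

    def test_or_is_exp_beta(self):
        iset = make_instrument_set([1.0, 1.0], 0.01, [0.4, 0.6], 1.0)
        est = ivw(iset)
        assert est.odds_ratio == np.exp(est.beta)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(2, 8))
def test_ivw_fixed_matches_wls_through_origin(seed, k):
    """IVW-fixed equals weighted least squares of outcome on exposure
    effects through the origin, solved independently by lstsq."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 1e-3] = 1e-3
    by = rng.normal(0.05, 0.05, k)
    sy = rng.uniform(0.01, 0.1, k)
    iset = make_instrument_set(bx, 0.01, by, sy)
    est = ivw(iset, "fixed")
    # independent route: scale rows by 1/sy and solve unweighted lstsq
    slope = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)[0][0]
    assert est.beta == pytest.approx(slope, rel=1e-10)
    assert est.se == pytest.approx(1 / np.sqrt(np.sum(bx**2 / sy**2)),
                                   rel=1e-10)


def test_ivw_and_q_match_metafor_fixed_effect(tmp_path, default_iset):
    """Cross-check against an independent meta-analysis implementation:
    IVW-fixed is a fixed-effect meta-analysis of the Wald ratios."""
    iset, _ = default_iset
    bx, sx, by, sy = iset.arrays()
    theta, se = by / bx, sy / np.abs(bx)
    data = tmp_path / "ratios.tsv"
    pd.DataFrame({"theta": theta, "se": se}).to_csv(data, sep="\t",
                                                    index=False)
    script = tmp_path / "fe.R"
    script.write_text(
        'suppressMessages(library(metafor))\n'
        f'd <- read.delim("{data}")\n'
        'f <- rma(yi=d$theta, sei=d$se, method="FE")\n'
        'cat(sprintf("%.12g %.12g %.12g", coef(f), f$se, f$QE))\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True).stdout.split()
    beta_r, se_r, q_r = map(float, out)
    est = ivw(iset, "fixed")
    assert est.beta == pytest.approx(beta_r, rel=1e-8)
    assert est.se == pytest.approx(se_r, rel=1e-8)
    assert est.extras["Q"] == pytest.approx(q_r, rel=1e-8)


class TestEgger:
    def test_exact_fit_recovers_line(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.01 + 0.5 * bx
        iset = make_instrument_set(bx, 0.001, by, 0.02)
        slope, intercept = egger(iset)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.01, abs=1e-10)

    def test_k2_rejected(self):
        iset = make_instrument_set([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValueError, match="k >= 3"):
            egger(iset)

    def test_orientation_independent(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.1, 0.05, 8)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        iset = make_instrument_set(bx, 0.01, by, 0.02)
        mixed = make_instrument_set(
            bx * np.where(np.arange(8) % 2 == 0, -1, 1), 0.01,
            by * np.where(np.arange(8) % 2 == 0, -1, 1), 0.02,
        )
        a, ia = egger(iset)
        b, ib = egger(mixed)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert ia.beta == pytest.approx(ib.beta, rel=1e-12)


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        bx = np.ones(5)
        by = np.array([1.0, 2, 3, 4, 5])
        iset = make_instrument_set(bx, 0.01, by, 1.0)
        assert weighted_median(iset, n_boot=10, seed=0).beta == pytest.approx(3.0)

    def test_interpolation_oracle(self):
        # ratios {0, 1, 10} with weights {1, 1, 8}: cumulative standardized
        # weights s = (0.05, 0.15, 0.6); interpolating to s = 0.5 gives
        # 1 + (0.5-0.15)/(0.6-0.15) * 9 = 8.0
        bx = np.array([1.0, 1.0, np.sqrt(8.0)])
        by = np.array([0.0, 1.0, 10.0]) * bx
        iset = make_instrument_set(bx, 0.01, by, 1.0)
        assert weighted_median(iset, n_boot=10, seed=0).beta == pytest.approx(
            8.0, abs=1e-12
        )

    def test_bootstrap_se_deterministic(self, default_iset):
        iset, _ = default_iset
        a = weighted_median(iset, n_boot=200, seed=7)
        b = weighted_median(iset, n_boot=200, seed=7)
        c = weighted_median(iset, n_boot=200, seed=8)
        assert a.se == b.se
        assert a.se != c.se


class TestMode:
    def test_degenerate_density(self):
        bx = np.array([1.0, 2.0, 4.0])
        iset = make_instrument_set(bx, 0.01, 0.7 * bx, 0.02)
        est = mode_estimate(iset, weighted=True, n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.7, abs=1e-12)

    def test_weighted_mode_follows_heavy_cluster(self):
        # cluster at 0.2 carries weights {9,9,9}; cluster at 0.8 only {1,1}
        bx = np.array([3.0, 3.0, 3.0, 1.0, 1.0])
        ratios = np.array([0.19, 0.2, 0.21, 0.79, 0.81])
        iset = make_instrument_set(bx, 0.01, ratios * bx, 1.0)
        est = mode_estimate(iset, weighted=True, n_boot=20, seed=0)
        assert abs(est.beta - 0.2) < 0.1

    def test_simple_equals_weighted_under_equal_weights(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.2, 0.25, 0.3, 0.9])
        iset = make_instrument_set(bx, 0.01, by, 1.0)
        a = mode_estimate(iset, weighted=False, n_boot=30, seed=5)
        b = mode_estimate(iset, weighted=True, n_boot=30, seed=5)
        assert a.beta == b.beta
        assert a.se == b.se


class TestMaxLikelihood:
    def test_matches_ivw_when_exposure_noise_vanishes(self, default_iset):
        iset, _ = default_iset
        table = iset.table.copy()
        table["SE_EXP"] = 1e-10
        from mr2step.harmonize import InstrumentSet
        tight = InstrumentSet("e", "o", table)
        assert max_likelihood(tight).beta == pytest.approx(
            ivw(tight, "fixed").beta, abs=1e-6
        )

    def test_consistent_two_point_data(self):
        iset = make_instrument_set([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        assert max_likelihood(iset).beta == pytest.approx(0.5, abs=1e-6)

    def test_optimum_improves_on_ivw_start(self, default_iset):
        iset, _ = default_iset
        from mr2step.estimators import _ml_profile_objective
        bx, sx, by, sy = iset.arrays()
        g = _ml_profile_objective(bx, sx, by, sy)
        est = max_likelihood(iset)
        assert g(est.beta) <= g(ivw(iset, "fixed").beta) + 1e-9


class TestEstimateAll:
    def test_full_panel_shape(self, default_iset):
        iset, _ = default_iset
        table = estimate_all(iset, seed=1, n_boot=50)
        assert len(table) == 6
        assert table["NSNP"].tolist() == [iset.k] * 6
        assert (table["STATUS"] == "ok").all()

    def test_or_column_is_exp_beta(self, default_iset):
        iset, _ = default_iset
        table = estimate_all(iset, seed=1, n_boot=50)
        np.testing.assert_allclose(table["OR"], np.exp(table["BETA"]),
                                   rtol=1e-12)

    def test_small_set_flags_robust_methods(self):
        iset = make_instrument_set([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        table = estimate_all(iset, seed=1, n_boot=10)
        flagged = table[table["STATUS"] == "insufficient_snps"]["METHOD"]
        assert set(flagged) == {"MR Egger", "Weighted median",
                                "Simple mode", "Weighted mode"}
        ok = table[table["STATUS"] == "ok"]["METHOD"]
        assert set(ok) == {"Inverse variance weighted", "Maximum likelihood"}

    def test_invariant_to_instrument_order(self, default_iset):
        iset, _ = default_iset
        from mr2step.harmonize import InstrumentSet
        shuffled = InstrumentSet(
            "e", "o",
            iset.table.sample(frac=1, random_state=3).reset_index(drop=True),
        )
        for fn in (lambda s: ivw(s).beta,
                   lambda s: egger(s)[0].beta,
                   lambda s: weighted_median(s, n_boot=5, seed=0).beta,
                   lambda s: max_likelihood(s).beta,
                   lambda s: mode_estimate(s, n_boot=5, seed=0).beta):
            assert fn(iset) == pytest.approx(fn(shuffled), rel=1e-9)
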