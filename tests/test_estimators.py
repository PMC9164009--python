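"""The six causal estimators, checked against oracles and the conservative set."""

import numpy as np
import pytest

from mrforge.errors import InsufficientInstrumentsError, InvalidInputError
from mrforge.estimators import (
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
    _weighted_median,
)
from mrforge.summary_io import HarmonizedInstrument

from conftest import make_instruments


def wls_oracle(bx, by, sy, intercept):
    """Independent weighted-least-squares fit via lstsq on the scaled design."""
    w = 1.0 / np.asarray(sy) ** 2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(len(bx)), bx]) if intercept else np.asarray(bx)[:, None]
    coef, *_ = np.linalg.lstsq(X * sw[:, None], np.asarray(by) * sw, rcond=None)
    return coef


def _flip(instruments):
    return [
        HarmonizedInstrument(i.variant_id, -i.beta_exp, i.se_exp, -i.beta_out, i.se_out)
        for i in instruments
    ]


class TestWaldRatio:
    def test_protective_conservative_instrument(self, conservative_instruments):
        ins = {i.variant_id: i for i in conservative_instruments}["rs1130864"]
        est = wald_ratio(ins)
        assert round(est.or_, 3) == 0.796
        assert round(est.ci_low, 3) == 0.639
        assert round(est.ci_high, 3) == 0.992
        assert est.pvalue == pytest.approx(0.043, abs=5e-4)

    def test_zero_outcome_beta_gives_unit_or(self):
        (ins,) = make_instruments([0.5], [0.0], [0.05])
        est = wald_ratio(ins)
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_direct_arithmetic(self):
        (ins,) = make_instruments([0.5], [0.1], [0.05])
        est = wald_ratio(ins)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_beta_rejected(self):
        (ins,) = make_instruments([0.0], [0.1], [0.05])
        with pytest.raises(InvalidInputError):
            wald_ratio(ins)

    def test_second_order_se_larger(self):
        (ins,) = make_instruments([0.5], [0.1], [0.05], sx=[0.1])
        assert wald_ratio(ins, second_order=True).se > wald_ratio(ins).se


class TestIVW:
    def test_conservative_set_random_effects(self, conservative_instruments):
        est = ivw(conservative_instruments)
        assert round(est.or_, 3) == 0.964
        assert round(est.ci_low, 3) == 0.830
        assert round(est.ci_high, 3) == 1.119
        assert est.pvalue == pytest.approx(0.628, abs=5e-4)

    def test_single_instrument_rejected(self):
        ins = make_instruments([0.5], [0.1], [0.05])
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw(ins)

    def test_identical_ratios_give_zero_q_and_fixed_equals_random(self):
        ins = make_instruments([0.2, 0.4], [0.06, 0.12], [0.02, 0.03])
        est_r = ivw(ins, model="multiplicative_random")
        est_f = ivw(ins, model="fixed")
        assert est_r.beta == pytest.approx(0.3)
        assert est_r.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert est_r.se == est_f.se

    def test_copies_of_one_snp_equal_its_wald_ratio(self):
        (single,) = make_instruments([0.3], [0.09], [0.02])
        est = ivw([single] * 5)
        assert est.beta == pytest.approx(wald_ratio(single).beta)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(3, 11))
            bx = rng.uniform(0.05, 0.4, n)
            by = rng.normal(0.2 * bx, 0.03)
            sy = rng.uniform(0.01, 0.05, n)
            est = ivw(make_instruments(bx, by, sy))
            (slope,) = wls_oracle(bx, by, sy, intercept=False)
            assert est.beta == pytest.approx(slope, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.4, 6)
        by = rng.normal(0.2 * bx, 0.03)
        sy = rng.uniform(0.01, 0.05, 6)
        est = ivw(make_instruments(bx, by, sy))
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_sign_flip_equivariance(self, random_instruments):
        ins = random_instruments(6, seed=3)
        assert ivw(_flip(ins)).beta == pytest.approx(ivw(ins).beta)


class TestEgger:
    def test_conservative_intercept(self, conservative_instruments):
        est = egger(conservative_instruments)
        assert round(est.extras["intercept"], 3) == -0.092
        assert round(est.extras["intercept_se"], 3) == 0.042
        assert est.extras["intercept_p"] == pytest.approx(0.158, abs=5e-4)

    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ins = make_instruments(bx, 0.5 * bx, [0.02] * 4)
        est = egger(ins)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            n = int(rng.integers(3, 11))
            bx = rng.uniform(0.05, 0.4, n)
            by = rng.normal(0.05 + 0.2 * bx, 0.03)
            sy = rng.uniform(0.01, 0.05, n)
            est = egger(make_instruments(bx, by, sy))
            intercept, slope = wls_oracle(bx, by, sy, intercept=True)
            assert est.beta == pytest.approx(slope, abs=1e-10)
            assert est.extras["intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))

    def test_sign_flip_equivariance(self, random_instruments):
        ins = random_instruments(7, seed=9)
        a, b = egger(ins), egger(_flip(ins))
        assert b.beta == pytest.approx(a.beta)
        assert b.extras["intercept"] == pytest.approx(a.extras["intercept"])


class TestWeightedMedian:
    def test_constant_ratios_return_that_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        ins = make_instruments(bx, 0.25 * bx, [0.01, 0.03, 0.02])
        est = weighted_median(ins, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.25)

    def test_interpolation_matches_hand_computation(self):
        # ratios 0.1, 0.2, 0.6 with equal weights: cumulative midpoints at
        # 1/6, 1/2, 5/6, so cumulative weight 0.5 lands exactly on 0.2
        ratios = np.array([0.1, 0.2, 0.6])
        assert _weighted_median(ratios, np.ones(3)) == pytest.approx(0.2)
        # unequal weights (1, 1, 2): midpoints 0.125, 0.375, 0.75; interpolating
        # 0.5 between 0.375 and 0.75 gives 0.2 + 0.4 * (0.125/0.375)
        expected = 0.2 + (0.6 - 0.2) * (0.5 - 0.375) / (0.75 - 0.375)
        assert _weighted_median(ratios, np.array([1.0, 1.0, 2.0])) == pytest.approx(expected)

    def test_seed_required(self, random_instruments):
        with pytest.raises(InvalidInputError):
            weighted_median(random_instruments(4, seed=0), n_boot=200, seed=None)

    def test_small_n_boot_warns(self, random_instruments):
        with pytest.warns(UserWarning):
            weighted_median(random_instruments(4, seed=0), n_boot=50, seed=1)

    def test_bootstrap_se_self_consistent(self, random_instruments):
        ins = random_instruments(10, seed=21)
        se1 = weighted_median(ins, n_boot=1000, seed=4).se
        se2 = weighted_median(ins, n_boot=4000, seed=5).se
        assert se1 == pytest.approx(se2, rel=0.15)

    def test_sign_flip_equivariance(self, random_instruments):
        ins = random_instruments(8, seed=2)
        a = weighted_median(ins, n_boot=500, seed=11)
        b = weighted_median(_flip(ins), n_boot=500, seed=11)
        assert b.beta == pytest.approx(a.beta)


class TestModeEstimate:
    def test_constant_ratios_return_that_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        ins = make_instruments(bx, 0.25 * bx, [0.01, 0.03, 0.02])
        est = mode_estimate(ins, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.25)

    def test_mode_ignores_minority_outliers(self):
        rng = np.random.default_rng(8)
        bx = np.full(10, 0.2)
        ratios = np.concatenate([rng.normal(0.5, 0.01, 8), [3.0, 3.1]])
        ins = make_instruments(bx, ratios * bx, np.full(10, 0.02))
        est = mode_estimate(ins, n_boot=200, seed=3)
        assert est.beta == pytest.approx(0.5, abs=0.1)

    def test_simple_equals_weighted_under_equal_weights(self):
        bx = np.array([0.2, 0.2, 0.2, 0.2])
        by = np.array([0.05, 0.06, 0.07, 0.2])
        ins = make_instruments(bx, by, np.full(4, 0.02))
        simple = mode_estimate(ins, weighted=False, n_boot=150, seed=2)
        weighted = mode_estimate(ins, weighted=True, n_boot=150, seed=2)
        assert simple.beta == pytest.approx(weighted.beta)

    def test_invalid_phi_rejected(self, random_instruments):
        with pytest.raises(InvalidInputError):
            mode_estimate(random_instruments(4, seed=0), phi=0.0, n_boot=200, seed=1)

    def test_sign_flip_equivariance(self, random_instruments):
        ins = random_instruments(8, seed=14)
        a = mode_estimate(ins, n_boot=300, seed=6)
        b = mode_estimate(_flip(ins), n_boot=300, seed=6)
        assert b.beta == pytest.approx(a.beta)


class TestEstimateInvariants:
    def test_or_and_ci_consistent(self, conservative_instruments):
        for est in (ivw(conservative_instruments), egger(conservative_instruments)):
            assert est.or_ == pytest.approx(np.exp(est.beta))
            assert est.ci_low <= est.or_ <= est.ci_high
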