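"""Closed-form model components: branch formulas, continuity, energy terms."""

import numpy as np
import pytest

from mgm_growth import (
    GSGMParams,
    MGMParams,
    ParameterError,
    ValidityDomainError,
    feeding_cost,
    growth_rate_compact,
    growth_rate_full,
    growth_rate_resting_form,
    gsgm_rate,
    ingestion_rate,
    maintenance_cost,
)
from mgm_growth.core import ingestion_rate_derivative


def make_male(**kw):
    base = dict(
        sex="male", e=0.8, E_M=6.0, E_S=2.7, alpha=2.0, beta=0.8,
        k=0.01, W_star=500.0, W_mat=400.0, S1=200.0, kF1=0.1, kF2=0.4,
        gamma_B=0.15, a_N=0.001, a_R=0.75, b_R=0.9, W_0=2.0,
    )
    base.update(kw)
    return MGMParams(**base)


def make_female(**kw):
    base = dict(
        sex="female", e=0.8, E_M=6.0, E_S=2.7, alpha=2.0, beta=0.8,
        k=0.01, W_star=550.0, W_mat=440.0, S1=200.0, kF1=0.1, kF2=0.4,
        gamma_BS=0.15, gamma_BR=0.25, a_N=0.001, a_R=0.75, b_R=0.9, W_0=2.0,
    )
    base.update(kw)
    return MGMParams(**base)


class TestIngestion:
    def test_juvenile_power_law_identity(self):
        p = make_male(alpha=1.0, beta=1.0, W_mat=100.0, W_star=300.0)
        assert ingestion_rate(50.0, p) == pytest.approx(50.0)

    def test_branches_agree_at_maturity(self):
        p = make_male()
        below = ingestion_rate(p.W_mat * (1 - 1e-12), p)
        above = ingestion_rate(p.W_mat * (1 + 1e-12), p)
        assert above == pytest.approx(below, rel=1e-9)
        assert ingestion_rate(p.W_mat, p) == pytest.approx(p.alpha * p.W_mat**p.beta)

    def test_adult_branch_peaks_at_W_star(self):
        # numeric maximization of the adult branch over a fine mass grid
        p = make_male(alpha=1.0, beta=1.0, W_mat=100.0, W_star=300.0, k=0.01)
        W = np.linspace(100.0, 600.0, 200001)
        S = ingestion_rate(W, p)
        assert W[np.argmax(S)] == pytest.approx(300.0, abs=0.01)

    def test_adult_derivative_matches_closed_form(self):
        p = make_male()
        W = np.linspace(p.W_mat * 1.01, p.W_star * 1.3, 50)
        h = 1e-4
        fd = (ingestion_rate(W + h, p) - ingestion_rate(W - h, p)) / (2 * h)
        expected = p.k * W ** (p.beta - 1) * (p.W_star - W)
        np.testing.assert_allclose(fd, expected, rtol=1e-6)

    def test_adult_branch_monotonicity_around_peak(self):
        p = make_male()
        rising = np.linspace(p.W_mat + 1, p.W_star - 1, 100)
        falling = np.linspace(p.W_star + 1, p.W_star * 1.5, 100)
        assert np.all(np.diff(ingestion_rate(rising, p)) > 0)
        assert np.all(np.diff(ingestion_rate(falling, p)) < 0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            ingestion_rate(0.0, make_male())


class TestFeedingCost:
    @pytest.mark.parametrize(
        "S,expected",
        [(0.0, 0.0), (150.0, 15.0), (300.0, 20.0 + 40.0), (200.0, 20.0)],
    )
    def test_hockey_stick_values(self, S, expected):
        p = make_male(kF1=0.1, kF2=0.4, S1=200.0)
        assert feeding_cost(S, p) == pytest.approx(expected)

    def test_monotone_nondecreasing(self):
        p = make_male()
        S = np.linspace(0, 1000, 2001)
        assert np.all(np.diff(feeding_cost(S, p)) >= 0)

    def test_negative_ingestion_rejected(self):
        with pytest.raises(ValueError):
            feeding_cost(-1.0, make_male())


class TestMaintenance:
    def test_linear_limit_all_basal(self):
        p = make_male(gamma_B=0.1, a_N=0.0)
        mc = maintenance_cost(100.0, p)
        assert mc.R_M == pytest.approx(10.0)
        assert mc.R_MN == pytest.approx(0.0)

    def test_negotiable_share_equals_aN_W(self):
        p = make_male(gamma_B=0.1, a_N=0.001)
        mc = maintenance_cost(100.0, p)
        assert mc.R_M == pytest.approx(10.0 / 0.9)
        assert mc.R_MN / mc.R_M == pytest.approx(0.001 * 100.0)
        # holds across a mass grid
        W = np.linspace(1.0, 900.0, 200)
        mc = maintenance_cost(W, p)
        np.testing.assert_allclose(mc.R_MN / mc.R_M, p.a_N * W, rtol=1e-12)

    def test_female_continuous_at_maturity(self):
        p = make_female()
        below = maintenance_cost(p.W_mat * (1 - 1e-12), p).R_M
        above = maintenance_cost(p.W_mat * (1 + 1e-12), p).R_M
        assert above == pytest.approx(below, rel=1e-9)

    def test_superlinearity(self):
        p = make_male(a_N=0.0005)
        for W in (50.0, 200.0, 400.0):
            ratio = maintenance_cost(2 * W, p).R_M / maintenance_cost(W, p).R_M
            assert ratio > 2.0
        p0 = make_male(a_N=0.0)
        assert maintenance_cost(400.0, p0).R_M / maintenance_cost(200.0, p0).R_M == pytest.approx(2.0)

    def test_singularity_raises_typed_error(self):
        p = make_male(a_N=0.001)
        with pytest.raises(ValidityDomainError):
            maintenance_cost(1000.0, p)


class TestGrowthRates:
    def test_full_rate_hand_value(self):
        # (e*S - R_F - R_M)/(E_M+E_S) with S=100 -> (80-10-30)/7
        p = make_male(
            alpha=1.0, beta=1.0, W_mat=200.0, e=0.8, E_M=5.0, E_S=2.0,
            kF1=0.1, kF2=0.1, S1=1000.0, gamma_B=0.3, a_N=0.0,
        )
        assert growth_rate_full(100.0, p) == pytest.approx((80 - 10 - 30) / 7.0)

    def test_rate_scales_inversely_with_growth_cost(self):
        p1 = make_male(E_M=5.0, E_S=2.0)
        p2 = make_male(E_M=10.0, E_S=4.0)
        assert growth_rate_full(100.0, p2) == pytest.approx(growth_rate_full(100.0, p1) / 2)

    def test_resting_form_hand_value(self):
        p = make_male(a_R=1.0, b_R=0.9, gamma_B=0.05, a_N=0.0005, E_S=2.7)
        expected = (100**0.9 - 0.05 * 100 / (1 - 0.05)) / 2.7
        assert growth_rate_resting_form(100.0, p) == pytest.approx(expected)

    def test_resting_form_requires_positive_overhead(self):
        with pytest.raises(ParameterError):
            growth_rate_resting_form(100.0, make_male(E_S=0.0))

    def test_compact_equals_full_under_parameter_fusion(self):
        # single feeding slope, juvenile branch, undifferentiated maintenance
        kF = 0.1
        p = make_male(kF1=kF, kF2=kF, S1=1e9, W_mat=5000.0, W_star=6000.0,
                      a_N=0.0001)
        a = (p.e - kF) * p.alpha / (p.E_M + p.E_S)
        c = p.gamma_B / (p.E_M + p.E_S)
        rng = np.random.default_rng(0)
        for W in rng.uniform(5.0, 900.0, 20):
            assert growth_rate_compact(W, a, p.beta, c, p.a_N) == pytest.approx(
                growth_rate_full(W, p), rel=1e-12
            )

    def test_compact_reduces_to_gsgm_without_negotiable_costs(self):
        g = GSGMParams(a=1.0, b=0.75, c=0.05, d=1.0)
        for W in (10.0, 100.0, 400.0):
            assert growth_rate_compact(W, 1.0, 0.75, 0.05, 0.0) == pytest.approx(
                gsgm_rate(W, g)
            )

    def test_gsgm_hand_value_and_root(self):
        g = GSGMParams(a=2.0, b=2 / 3, c=0.2, d=1.0)
        assert gsgm_rate(1.0, g) == pytest.approx(1.8)
        W_inf = (g.a / g.c) ** (1 / (g.d - g.b))
        assert gsgm_rate(W_inf, g) == pytest.approx(0.0, abs=1e-9)


class TestValidation:
    def test_gsgm_degenerate_exponents_rejected(self):
        with pytest.raises(ParameterError):
            GSGMParams(a=1.0, b=0.75, c=0.1, d=0.75)

    def test_gsgm_d_above_one_flagged(self):
        with pytest.warns(UserWarning):
            GSGMParams(a=1.0, b=0.75, c=0.1, d=1.2)

    def test_phi_fixed_at_ad_libitum(self):
        with pytest.raises(ParameterError):
            make_male(phi=0.5)

    @pytest.mark.parametrize(
        "bad",
        [dict(e=0.0), dict(e=1.5), dict(E_M=-1.0), dict(kF1=0.5, kF2=0.2),
         dict(W_0=500.0), dict(a_N=-0.1), dict(gamma_B=None)],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_male(**bad)

    def test_maturity_beyond_singularity_rejected(self):
        with pytest.raises(ParameterError):
            make_male(a_N=0.01, W_mat=400.0)


class TestSerialization:
    def test_yaml_round_trip(self, female_params):
        text = female_params.to_yaml()
        assert MGMParams.from_yaml(text) == female_params

    def test_unknown_keys_rejected(self, male_params):
        d = male_params.to_dict()
        d["mystery_knob"] = 1.0
        with pytest.raises(ParameterError):
            MGMParams.from_dict(d)
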