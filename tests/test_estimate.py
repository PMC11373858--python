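"""Calibration stages: allometry fits, hockey stick, inverse optimization."""

import numpy as np
import pandas as pd
import pytest

from mgm_growth import (
    fit_hockey_stick,
    fit_ingestion_adult,
    fit_ingestion_juvenile,
    fit_inverse_growth,
    infer_feeding_cost_series,
)
from mgm_growth.estimate import _adult_branch
from tests.test_preprocess import _series


def power_series(id_, alpha, beta, sex="male", n=10, mat=None):
    ages = np.arange(0, 3.5 * n, 3.5)
    W = np.geomspace(5, 400, n)
    s = _series(id_, sex, ages, W)
    s.W_at_S = (W[:-1] + W[1:]) / 2
    s.S = alpha * s.W_at_S**beta
    if mat is not None:
        s.maturity_age, s.maturity_mass = mat
    return s


class TestJuvenileIngestion:
    def test_exact_power_data_machine_precision(self):
        fits = fit_ingestion_juvenile([power_series(f"M{i}", 2.0, 0.8) for i in range(3)])
        assert fits.params["beta"] == pytest.approx(0.8, abs=1e-10)
        assert fits.params["alpha"] == pytest.approx(2.0, rel=1e-10)
        assert fits.sre["log10_alpha"] == pytest.approx(0.0, abs=1e-12)

    def test_individual_intercept_spread_recovered(self):
        rng = np.random.default_rng(0)
        series = [
            power_series(f"M{i}", 2.0 * 10 ** rng.normal(0, 0.1), 0.8)
            for i in range(40)
        ]
        fits = fit_ingestion_juvenile(series)
        assert fits.params["beta"] == pytest.approx(0.8, abs=1e-9)
        re = np.array(list(fits.random_effects["log10_alpha"].values()))
        assert re.std(ddof=1) == pytest.approx(0.1, rel=0.35)

    def test_mixed_sex_input_rejected(self):
        series = [power_series("M1", 2.0, 0.8, "male"),
                  power_series("F1", 2.0, 0.8, "female")]
        with pytest.raises(ValueError, match="per sex"):
            fit_ingestion_juvenile(series)

    def test_sparse_individuals_dropped(self):
        good = [power_series(f"M{i}", 2.0, 0.8) for i in range(2)]
        sparse = power_series("M9", 2.0, 0.8, n=3)  # 2 ingestion records only
        fits = fit_ingestion_juvenile(good + [sparse])
        assert fits.extras["n_individuals"] == 2


class TestAdultIngestion:
    def test_noise_free_recovery(self):
        alpha, beta, k, W_star, W_mat = 4.0, 0.8, 0.016, 520.0, 420.0
        ages = np.arange(40, 40 + 3.5 * 12, 3.5)
        W = np.linspace(425, 560, ages.size)
        s = _series("F1", "female", ages, W)
        s.W_at_S = (W[:-1] + W[1:]) / 2
        s.S = _adult_branch(s.W_at_S, alpha, beta, k, W_star, W_mat)
        s.maturity_age, s.maturity_mass = 38.0, W_mat
        fits = fit_ingestion_adult([s], alpha, beta)
        assert fits.params["k"] == pytest.approx(k, rel=0.01)
        assert fits.params["W_star"] == pytest.approx(W_star, rel=0.01)

    def test_requires_post_maturity_records(self):
        with pytest.raises(ValueError):
            fit_ingestion_adult([power_series("M1", 2.0, 0.8)], 2.0, 0.8)


class TestFeedingCostInference:
    def test_hand_arithmetic(self):
        s = _series("A", "male", [0.0, 2.0], [100.0, 100.0])
        s.S = np.array([500.0])
        s.W_at_S = np.array([100.0])
        s.dWdt_at_S = np.array([10.0])
        # R_F = 0.8*500 - 5*10 - 100 = 250 with a_R*W^b_R = 100
        rf = infer_feeding_cost_series([s], e=0.8, E_M=5.0, a_R=100.0 / 100.0**0.9,
                                       b_R=0.9)
        assert rf["R_F_J_d"].iloc[0] == pytest.approx(250.0)

    def test_non_growing_limit(self):
        s = _series("A", "male", [0.0, 2.0], [100.0, 100.0])
        s.S = np.array([500.0])
        s.W_at_S = np.array([100.0])
        s.dWdt_at_S = np.array([0.0])
        rf = infer_feeding_cost_series([s], e=0.8, E_M=5.0, a_R=0.0, b_R=0.9)
        assert rf["R_F_J_d"].iloc[0] == pytest.approx(0.8 * 500.0)


class TestHockeyStick:
    @staticmethod
    def hockey(S, kF1, kF2, S1):
        return np.where(S <= S1, kF1 * S, kF1 * S1 + kF2 * (S - S1))

    def test_exact_recovery_noiseless(self):
        # the true break sits on an observed S value, so the profile can hit it
        S = np.arange(10.0, 501.0, 10.0)
        fr = fit_hockey_stick(S, self.hockey(S, 0.1, 0.4, 200.0))
        assert fr.params["kF1"] == pytest.approx(0.1, abs=1e-8)
        assert fr.params["kF2"] == pytest.approx(0.4, abs=1e-8)
        assert fr.params["S1"] == pytest.approx(200.0, rel=1e-6)

    def test_single_line_flags_no_break(self):
        S = np.linspace(10, 500, 40)
        fr = fit_hockey_stick(S, 0.25 * S)
        assert fr.message == "no break detected"
        assert fr.params["kF1"] == pytest.approx(fr.params["kF2"], abs=1e-6)

    def test_noisy_breakpoint_recovery(self):
        rng = np.random.default_rng(12)
        errs = []
        for _ in range(20):
            S = rng.uniform(10, 600, 120)
            RF = self.hockey(S, 0.1, 0.4, 250.0) * (1 + 0.1 * rng.standard_normal(120))
            fr = fit_hockey_stick(S, RF)
            errs.append(fr.params["S1"] / 250.0 - 1)
        assert np.abs(np.mean(errs)) < 0.15

    def test_grouped_fit_removes_individual_block_shifts(self):
        # each individual's cloud is tilted by its own baseline slope;
        # pooling confounds it, the grouped fit does not
        rng = np.random.default_rng(5)
        S_all, RF_all, ids = [], [], []
        for i, tilt in enumerate(rng.normal(0, 0.05, 10)):
            S = np.linspace(20, 500, 30)
            RF = self.hockey(S, 0.1 + tilt, 0.4 + tilt, 250.0)
            S_all.append(S), RF_all.append(RF), ids.append([f"I{i}"] * 30)
        fr = fit_hockey_stick(
            np.concatenate(S_all), np.concatenate(RF_all),
            groups=np.concatenate(ids),
        )
        assert fr.params["kF1"] == pytest.approx(0.1, abs=0.02)
        assert fr.params["kF2"] == pytest.approx(0.4, abs=0.05)
        assert fr.params["S1"] == pytest.approx(250.0, rel=0.1)
        assert set(fr.random_effects["kF1"]) == {f"I{i}" for i in range(10)}

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            fit_hockey_stick([5.0] * 10, [1.0] * 10)


class TestInverseGrowth:
    def test_noise_free_male_recovery(self, clean_dataset, clean_series):
        raw, meta = clean_dataset
        males = [s for s in clean_series if s.sex == "male"]
        fr = fit_inverse_growth(males, a_R=0.75, b_R=0.9, sex="male",
                                E_M=6.0, per_individual=False, seed=0)
        t = meta["templates"]["male"]
        assert fr.params["E_S"] == pytest.approx(t["E_S"], rel=0.02)
        assert fr.params["gamma_B"] == pytest.approx(t["gamma_B"], rel=0.02)
        assert fr.params["a_N"] == pytest.approx(t["a_N"], rel=0.05)

    def test_objective_at_truth_beats_perturbations(self, clean_dataset, clean_series):
        """Local-optimality probe around the recovered optimum."""
        raw, meta = clean_dataset
        males = [s for s in clean_series if s.sex == "male"]
        fr = fit_inverse_growth(males, a_R=0.75, b_R=0.9, sex="male",
                                E_M=6.0, per_individual=False, seed=0)
        from mgm_growth.estimate import _maintenance_stub, _predict_mass
        from mgm_growth.preprocess import sex_average
        avg = sex_average(males)["male"]
        occ = avg[np.isfinite(avg["W_raw_mg"])]
        ages = occ["age_d"].to_numpy(float)
        W_obs = occ["W_raw_mg"].to_numpy(float)

        def sse(theta):
            p = _maintenance_stub("male", theta, fr.extras["W_mat"],
                                  fr.extras["W_0"], 0.75, 0.9, 6.0)
            return float(((_predict_mass(p, ages) - W_obs) ** 2).sum())

        best = dict(E_S=fr.params["E_S"], gamma_B=fr.params["gamma_B"],
                    a_N=fr.params["a_N"])
        base = sse(best)
        rng = np.random.default_rng(2)
        for _ in range(25):
            pert = {k: v * float(rng.uniform(0.9, 1.1)) for k, v in best.items()}
            assert sse(pert) >= base - 1e-9

    def test_sre_consistency_with_stored_random_effects(self, clean_pipeline):
        for sex, stages in clean_pipeline["fits"].items():
            fr = stages["inverse"]
            for name, res in fr.random_effects.items():
                vals = np.array(list(res.values()))
                if vals.size >= 2 and fr.params[name] != 0:
                    expected = vals.std(ddof=1) / abs(fr.params[name])
                    assert fr.sre[name] == pytest.approx(expected, rel=1e-12)
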