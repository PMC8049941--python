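"""Explanatory-model fitting: mixed logistic with asymptotes, screening,
subset search, cross-validation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import check_grad
from scipy.special import expit

from apiat.calibration import (
    DegenerateDataError,
    _marginal_loglik_and_grad,
    build_design,
    cv_accuracy,
    fit_model,
    fit_split_then_joint,
    optimize_asymptotes,
    screen_predictors,
    subset_search,
)
from apiat.irt import COEFFICIENT_NAMES, DEFAULT_COEFFICIENTS, ModelParams, calibrate_bank
from apiat.simulate import calibration_session_sampler, simulate_cohort

JOINT_TERMS = list(COEFFICIENT_NAMES[1:])


def _simulate_table(bank, feats, n_participants, seed, c=0.3, d=0.95,
                    sigma=1.0, coef=None, items_per_level=6):
    """Draw long-format responses from the explanatory model itself."""
    coef = coef or DEFAULT_COEFFICIENTS
    cal = {it.item_id: it for it in calibrate_bank(
        bank, ModelParams(coefficients=coef)
    )}
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(n_participants, sd=sigma, seed=seed)
    alloc = {lvl: items_per_level for lvl in bank.config.levels}
    rows = []
    for pid, theta in cohort.thetas.items():
        for item in calibration_session_sampler(bank, alloc, rng):
            p = c + (d - c) * expit(cal[item.item_id].easiness + theta)
            rows.append((pid, item.item_id, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "correct"])


@pytest.fixture(scope="module")
def sim_data(calibration_bank, calibration_features):
    return _simulate_table(calibration_bank, calibration_features, 150, seed=42)


class TestFitModel:
    def test_plain_logistic_limit_matches_statsmodels(
        self, calibration_bank, calibration_features, sim_data
    ):
        """c=0, d=1, sigma=0 reduces to ordinary logistic regression."""
        subset = ["correct:level", "incorrect:level"]
        fit = fit_model(sim_data, subset, c=0.0, d=1.0,
                        features=calibration_features, sigma_zero=True)
        merged = sim_data.merge(calibration_features, on="item_id")
        X = build_design(merged, subset)
        oracle = sm.GLM(
            merged["correct"].to_numpy(), X, family=sm.families.Binomial()
        ).fit()
        ours = [fit.coefficients[n] for n in ("intercept", *subset)]
        assert np.allclose(ours, oracle.params, atol=1e-4)
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-6)

    def test_gradient_matches_finite_differences(
        self, calibration_features, sim_data
    ):
        merged = sim_data.merge(calibration_features, on="item_id")
        y = merged["correct"].to_numpy(dtype=float)
        X = build_design(merged, ["correct:level"])
        pids, codes = np.unique(merged["participant_id"], return_inverse=True)
        t, w = np.polynomial.hermite.hermgauss(15)
        log_w = np.log(w) - 0.5 * np.log(np.pi)
        args = (X, y, codes, len(pids), 0.3, 0.95, t, log_w, True)
        x0 = np.array([0.3, -0.1, 0.8])
        err = check_grad(
            lambda v: _marginal_loglik_and_grad(v, *args)[0],
            lambda v: _marginal_loglik_and_grad(v, *args)[1],
            x0,
        )
        assert err < 1e-4

    def test_recovers_generating_coefficients(
        self, calibration_bank, calibration_features
    ):
        data = _simulate_table(calibration_bank, calibration_features, 200, seed=5)
        fit = fit_model(data, JOINT_TERMS, c=0.3, d=0.95,
                        features=calibration_features)
        assert fit.converged
        for name in ("intercept", *JOINT_TERMS):
            est = fit.coefficients[name]
            se = fit.standard_errors[name]
            assert abs(est - DEFAULT_COEFFICIENTS[name]) <= 3 * se
        assert 0.6 < fit.participant_effect_sd < 1.4

    def test_null_model_balanced_data_has_small_intercept(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(50)], 40),
                "item_id": ["i"] * 2000,
                "correct": rng.integers(0, 2, size=2000),
            }
        )
        fit = fit_model(data, (), c=0.0, d=1.0, sigma_zero=True)
        assert abs(fit.coefficients["intercept"]) < 0.15

    def test_bic_identity(self, calibration_features, sim_data):
        fit = fit_model(sim_data, ["correct:level"], features=calibration_features)
        assert fit.bic == pytest.approx(
            -2 * fit.log_likelihood + fit.n_params * np.log(fit.n_obs)
        )

    def test_degenerate_data_rejected(self):
        data = pd.DataFrame(
            {"participant_id": ["a", "b"], "item_id": ["i", "j"], "correct": [1, 1]}
        )
        with pytest.raises(DegenerateDataError):
            fit_model(data, ())


class TestOptimizeAsymptotes:
    def test_recovers_simulated_asymptotes(
        self, calibration_bank, calibration_features
    ):
        data = _simulate_table(
            calibration_bank, calibration_features, 150, seed=9,
            c=0.3, d=0.95,
        )
        # profile surfaces in (c, d) are flat near the ceiling, so recovery
        # is to the generating grid point or an adjacent cell
        fit = optimize_asymptotes(
            data, JOINT_TERMS,
            grid=([0.1, 0.2, 0.3, 0.4], [0.85, 0.9, 0.95, 1.0]),
            features=calibration_features,
        )
        assert abs(fit.guessing - 0.3) <= 0.1
        assert fit.inattention >= 0.9

    def test_profile_argmax_property(self, calibration_features, sim_data):
        grid = ([0.0, 0.3], [0.9, 1.0])
        best = optimize_asymptotes(
            sim_data, ["correct:level"], grid=grid,
            features=calibration_features,
        )
        for c in grid[0]:
            for d in grid[1]:
                fit = fit_model(sim_data, ["correct:level"], c=c, d=d,
                                features=calibration_features, compute_se=False)
                assert best.log_likelihood >= fit.log_likelihood - 1e-6


def _signal_noise_data(n=400, seed=0):
    """Responses driven by one feature; two pure-noise features."""
    rng = np.random.default_rng(seed)
    n_items = 60
    feats = pd.DataFrame(
        {
            "item_id": [f"i{j}" for j in range(n_items)],
            "signal": rng.normal(size=n_items),
            "noise_a": rng.normal(size=n_items),
            "noise_b": rng.normal(size=n_items),
        }
    )
    rows = []
    for p in range(n // n_items * 2):
        for j in rng.choice(n_items, size=n_items // 2, replace=False):
            eta = 2.5 * feats.loc[j, "signal"]
            rows.append(
                (f"p{p}", feats.loc[j, "item_id"], int(rng.random() < expit(eta)))
            )
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "correct"]), feats


class TestScreenPredictors:
    def test_signal_feature_ranked_first(self):
        data, feats = _signal_noise_data()
        hits = 0
        for seed in range(10):
            ranked = screen_predictors(
                data, ["signal", "noise_a", "noise_b"], rng=seed, features=feats
            )
            hits += ranked[0] == "signal"
        assert hits >= 9

    def test_constant_feature_importance_negligible(self):
        data, feats = _signal_noise_data(seed=3)
        feats["flat"] = 1.0
        ranked = screen_predictors(
            data, ["signal", "flat", "noise_a"], rng=0, features=feats
        )
        assert ranked[0] == "signal"
        assert ranked[-1] in ("flat", "noise_a")

    def test_n_keep_none_returns_full_ranking(self):
        data, feats = _signal_noise_data(seed=1)
        ranked = screen_predictors(
            data, ["signal", "noise_a", "noise_b"], n_keep=None,
            rng=0, features=feats,
        )
        assert sorted(ranked) == ["noise_a", "noise_b", "signal"]

    def test_too_few_candidates_rejected(self):
        data, feats = _signal_noise_data(seed=2)
        with pytest.raises(ValueError):
            screen_predictors(data, ["signal"], rng=0, features=feats)


class TestSubsetSearch:
    def test_true_predictor_selected_and_beats_null(self):
        data, feats = _signal_noise_data(seed=4)
        best, table = subset_search(
            data, ["signal", "noise_a"], c=0.0, d=1.0,
            features=feats, sigma_zero=True,
        )
        assert "signal" in best.feature_subset
        null_bic = table.loc[table["size"] == 0, "bic"].iloc[0]
        assert best.bic < null_bic

    def test_table_enumerates_all_subsets(self):
        data, feats = _signal_noise_data(seed=5)
        _, table = subset_search(
            data, ["signal", "noise_a", "noise_b"], c=0.0, d=1.0,
            features=feats, sigma_zero=True,
        )
        assert len(table) == 2**3

    def test_budget_exceeded_advises_max_size(self):
        data, feats = _signal_noise_data(seed=6)
        with pytest.raises(ValueError, match="max_size"):
            subset_search(data, ["signal", "noise_a"], budget=2, features=feats)


class TestCvAccuracy:
    def test_strong_signal_approaches_one(self):
        data, feats = _signal_noise_data(seed=7)
        acc = cv_accuracy(data, ["signal"], k_folds=5, rng=0,
                          c=0.0, d=1.0, features=feats, sigma_zero=True)
        assert acc > 0.75

    def test_zero_signal_near_chance(self):
        rng = np.random.default_rng(8)
        n = 2000
        data = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(40)], n // 40),
                "item_id": [f"i{j % 50}" for j in range(n)],
                "correct": rng.integers(0, 2, size=n),
            }
        )
        feats = pd.DataFrame(
            {"item_id": [f"i{j}" for j in range(50)],
             "x": np.random.default_rng(9).normal(size=50)}
        )
        acc = cv_accuracy(data, ["x"], k_folds=5, rng=0, c=0.0, d=1.0,
                          features=feats, sigma_zero=True)
        assert abs(acc - 0.5) < 0.05

    def test_participant_effects_help_when_sd_large(
        self, calibration_bank, calibration_features
    ):
        data = _simulate_table(
            calibration_bank, calibration_features, 80, seed=11, sigma=2.0
        )
        kwargs = dict(k_folds=5, rng=0, c=0.3, d=0.95,
                      features=calibration_features)
        with_eff = cv_accuracy(data, ["correct:level"],
                               with_participant_effects=True, **kwargs)
        without = cv_accuracy(data, ["correct:level"],
                              with_participant_effects=False, **kwargs)
        assert with_eff >= without

    def test_invalid_folds_rejected(self, calibration_features, sim_data):
        with pytest.raises(ValueError):
            cv_accuracy(sim_data, [], k_folds=1, features=calibration_features)


def test_split_then_joint_driver(calibration_bank, calibration_features):
    data = _simulate_table(calibration_bank, calibration_features, 80, seed=13)
    fits = fit_split_then_joint(data, features=calibration_features)
    assert set(fits) == {"correct", "incorrect", "joint"}
    # separate fits see only their own probe-accuracy subset
    assert fits["correct"].n_obs + fits["incorrect"].n_obs == fits["joint"].n_obs
    assert set(fits["joint"].feature_subset) == set(JOINT_TERMS)
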