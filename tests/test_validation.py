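"""Accuracy statistics, AUC, calibration, bootstrap SDs, refits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from borealrange.validation import (
    ValidationSet,
    aggregate_townships,
    auc,
    calibration_fit,
    confusion,
    resample_rate_sd,
    sensitivity_specificity,
    tss,
    validate,
)


def make_vs(observed, probability):
    return ValidationSet(
        pd.DataFrame(
            {
                "cell_id": np.arange(len(observed)),
                "observed": observed,
                "probability": probability,
            }
        )
    )


def brute_force_auc(observed, scores):
    """Pair-counting oracle: P(score_presence > score_absence), ties 1/2."""
    obs = np.asarray(observed, dtype=bool)
    s_pos, s_neg = np.asarray(scores)[obs], np.asarray(scores)[~obs]
    diff = s_pos[:, None] - s_neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size


class TestConfusion:
    def test_perfect_predictions(self):
        vs = make_vs([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        c = confusion(vs, 0.5)
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 2)

    def test_threshold_zero_makes_all_positive(self):
        vs = make_vs([1, 0, 0], [0.4, 0.2, 0.9])
        c = confusion(vs, 0.0)
        assert c.tn == 0 and c.fp == 2

    def test_ten_record_fixture_enumeration(self):
        rng = np.random.default_rng(9)
        obs = rng.integers(0, 2, 10)
        p = rng.random(10)
        c = confusion(make_vs(obs, p), 0.5)
        pred = p >= 0.5
        assert c.tp == int(((obs == 1) & pred).sum())
        assert c.fp == int(((obs == 0) & pred).sum())
        assert c.tn == int(((obs == 0) & ~pred).sum())
        assert c.fn == int(((obs == 1) & ~pred).sum())
        assert c.tp + c.fp + c.tn + c.fn == 10
        sens, spec = sensitivity_specificity(c)
        assert sens == pytest.approx(c.tp / (c.tp + c.fn))
        assert spec == pytest.approx(c.tn / (c.tn + c.fp))


class TestTSS:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.79, 0.84, 0.63), (0.96, 0.62, 0.58), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)],
    )
    def test_values(self, sens, spec, expected):
        assert tss(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_identity_with_confusion(self):
        vs = make_vs([1, 1, 1, 0, 0], [0.9, 0.6, 0.2, 0.8, 0.1])
        sens, spec = sensitivity_specificity(confusion(vs, 0.5))
        assert tss(sens, spec) == pytest.approx(sens + spec - 1, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tss(1.2, 0.5)


class TestAUC:
    def test_perfect_separation_gives_one(self):
        vs = make_vs([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc(vs) == 1.0

    def test_all_ties_give_half(self):
        vs = make_vs([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc(vs) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = rng.integers(6, 300)
            obs = rng.integers(0, 2, n)
            if obs.min() == obs.max():
                obs[0] = 1 - obs[0]
            p = rng.choice(np.round(rng.random(20), 2), n)  # ties likely
            vs = make_vs(obs, p)
            assert auc(vs) == pytest.approx(brute_force_auc(obs, p), abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(0, 2, 50)
        if obs.min() == obs.max():
            obs[0] = 1 - obs[0]
        p = rng.random(50)
        a1 = auc(make_vs(obs, p))
        a2 = auc(make_vs(obs, expit(4 * p - 2)))  # strictly increasing map
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auc(make_vs([1, 1, 1], [0.2, 0.5, 0.7]))


class TestCalibration:
    def test_logit_regressor_recovers_identity_on_self_consistent_data(self):
        # when the regression runs on the logit scale the model family
        # contains the identity curve, so a self-consistent sample recovers
        # slope 1 / intercept 0 up to sampling noise
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.random(10_000) < p).astype(int)
        cal = calibration_fit(make_vs(y, p), regressor="logit")
        assert cal.slope == pytest.approx(1.0, abs=0.1)
        assert cal.intercept == pytest.approx(0.0, abs=0.12)
        grid = np.linspace(0.1, 0.9, 81)
        assert np.abs(cal.curve(grid) - grid).max() < 0.03

    def test_probability_regressor_slope_matches_logistic_rescaling(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.random(10_000) < p).astype(int)
        cal = calibration_fit(make_vs(y, p))
        assert 4.5 <= cal.slope <= 6.5
        assert cal.converged and not cal.separation

    def test_constant_predictor_flagged_degenerate(self):
        vs = make_vs([1, 0, 1, 0], [0.4, 0.4, 0.4, 0.4])
        cal = calibration_fit(vs)
        assert cal.degenerate and cal.slope == 0.0

    def test_perfect_separation_flagged_unbounded(self):
        vs = make_vs([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        cal = calibration_fit(vs)
        assert cal.separation and np.isinf(cal.slope)

    def test_eight_point_fixture_matches_newton_oracle(self):
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1], dtype=float)
        x = np.array([0.1, 0.3, 0.35, 0.5, 0.55, 0.7, 0.75, 0.9])
        cal = calibration_fit(make_vs(y, x))

        # independent Newton-Raphson on the two-parameter log-likelihood
        beta = np.zeros(2)
        X = np.column_stack([np.ones_like(x), x])
        for _ in range(50):
            mu = expit(X @ beta)
            grad = X.T @ (y - mu)
            hess = -(X * (mu * (1 - mu))[:, None]).T @ X
            beta = beta - np.linalg.solve(hess, grad)
        assert cal.intercept == pytest.approx(beta[0], abs=1e-6)
        assert cal.slope == pytest.approx(beta[1], abs=1e-6)


class TestBootstrapSD:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        vs = make_vs(rng.integers(0, 2, 60), rng.random(60))
        a = resample_rate_sd(vs, 0.5, reps=200, seed=11)
        b = resample_rate_sd(vs, 0.5, reps=200, seed=11)
        assert a == b

    def test_all_presence_set_has_undefined_specificity(self):
        vs = make_vs([1] * 20, np.linspace(0.1, 0.9, 20))
        sens_sd, spec_sd = resample_rate_sd(vs, 0.5, reps=200, seed=0)
        assert np.isfinite(sens_sd) and np.isnan(spec_sd)

    def test_matches_binomial_approximation_at_large_n(self):
        # sensitivity estimator is a binomial proportion: sd ~ sqrt(p(1-p)/n)
        rng = np.random.default_rng(8)
        n = 4000
        obs = np.ones(n, dtype=int)
        correct = 0.8
        p = np.where(rng.random(n) < correct, 0.9, 0.1)  # sens ~= 0.8
        vs = make_vs(obs, p)
        sens_sd, _ = resample_rate_sd(vs, 0.5, reps=1000, seed=1)
        sens = (p >= 0.5).mean()
        analytic = np.sqrt(sens * (1 - sens) / n)
        assert sens_sd == pytest.approx(analytic, rel=0.2)

    def test_too_few_reps_rejected(self):
        vs = make_vs([1, 0], [0.9, 0.1])
        with pytest.raises(ValueError):
            resample_rate_sd(vs, 0.5, reps=10)


class TestValidateRow:
    def test_full_row_internally_consistent(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, 300)
        obs = (rng.random(300) < p).astype(int)
        stats = validate(make_vs(obs, p), threshold=0.73, reps=200, seed=0)
        assert stats.n == 300
        assert stats.prevalence == pytest.approx(obs.mean())
        assert stats.tss == pytest.approx(stats.sensitivity + stats.specificity - 1, abs=1e-12)
        assert 0.5 < stats.auc <= 1.0


class TestTownships:
    def test_presence_is_sticky_across_years(self):
        surveys = pd.DataFrame(
            {
                "township": ["A", "A", "A", "B", "B"],
                "year": [1971, 1975, 1979, 1972, 1978],
                "presence": [0, 1, 0, 0, 0],
            }
        )
        out = aggregate_townships(surveys)
        a = out[out.township == "A"].set_index("year")["presence"]
        assert a.loc[1971] == 0 and a.loc[1975] == 1 and a.loc[1979] == 1
        assert (out[out.township == "B"]["presence"] == 0).all()

    def test_any_presence_in_year_scores_township(self):
        surveys = pd.DataFrame(
            {"township": ["A", "A"], "year": [1980, 1980], "presence": [0, 1]}
        )
        assert aggregate_townships(surveys)["presence"].tolist() == [1]

    def test_non_sticky_option(self):
        surveys = pd.DataFrame(
            {"township": ["A", "A"], "year": [1971, 1975], "presence": [1, 0]}
        )
        out = aggregate_townships(surveys, sticky=False)
        assert out["presence"].tolist() == [1, 0]
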