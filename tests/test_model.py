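import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rspfit.model import (
    ModelSpec,
    ResourceSelectionModel,
    fd_hessian,
    linear_predictor,
    parse_term,
    selection_prob,
    standard_errors_from_hessian,
    use_available_loglik,
)

MANED_WOLF = ModelSpec("logistic", ["agDist", "(agDist)^2", "closed", "pasture"])
MANED_WOLF_BETA = np.array([2.391, -1.267, 0.122, -2.913, -1.176])
PUMA = ModelSpec("logistic", ["closed", "natural"])
PUMA_BETA = np.array([-4.084, 25.620, 2.508])


class FakeData:
    """Minimal use-availability container for likelihood unit tests."""

    def __init__(self, used: pd.DataFrame, avail: pd.DataFrame):
        self._u, self._a = used, avail

    def used_table(self):
        return self._u

    def available_table(self):
        return self._a


class TestTerms:
    def test_parse_main_product_power(self):
        assert parse_term("closed").kind == "main"
        t = parse_term("natural*MainroadDist")
        assert t.kind == "product" and t.names == ("natural", "MainroadDist")
        p = parse_term("(agDist)^2")
        assert p.kind == "power" and p.exponent == 2
        assert p.label == "(agDist)^2"

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec("logistic", ["closed", "closed"])

    def test_intercept_only_for_logistic(self):
        assert ModelSpec("logistic", ["closed"]).k == 2
        assert ModelSpec("exponential", ["closed"]).k == 1


class TestLinearPredictor:
    def test_maned_wolf_at_reference_row(self):
        row = pd.DataFrame({"agDist": [0.0], "closed": [0.0], "pasture": [0.0]})
        eta = linear_predictor(MANED_WOLF, MANED_WOLF_BETA, row)
        assert eta[0] == pytest.approx(2.391, abs=1e-12)

    def test_all_zero_beta(self):
        row = pd.DataFrame({"closed": [0.7], "natural": [0.3]})
        assert linear_predictor(PUMA, np.zeros(3), row)[0] == 0.0

    def test_puma_half_closed_all_natural(self):
        row = pd.DataFrame({"closed": [0.5], "natural": [1.0]})
        eta = linear_predictor(PUMA, PUMA_BETA, row)
        assert eta[0] == pytest.approx(-4.084 + 25.620 * 0.5 + 2.508, abs=1e-12)
        assert eta[0] == pytest.approx(11.234, abs=1e-12)

    def test_interaction_term_multiplies(self):
        spec = ModelSpec("exponential", ["natural*MainroadDist"])
        row = pd.DataFrame({"natural": [0.5], "MainroadDist": [3.0]})
        assert linear_predictor(spec, [2.0], row)[0] == pytest.approx(3.0)

    def test_missing_covariate_named(self):
        with pytest.raises(KeyError, match="natural"):
            linear_predictor(PUMA, PUMA_BETA, pd.DataFrame({"closed": [0.0]}))

    def test_wrong_beta_length(self):
        with pytest.raises(ValueError, match="entries"):
            linear_predictor(PUMA, [0.0, 1.0], pd.DataFrame({"closed": [0], "natural": [0]}))


class TestSelectionProb:
    def test_reference_values(self):
        assert selection_prob("logistic", 0.0) == pytest.approx(0.5)
        assert selection_prob("exponential", 0.0) == pytest.approx(1.0)
        # inverse-logit of the puma intercept, high-precision reference
        assert selection_prob("logistic", -4.084) == pytest.approx(
            0.016561082719094122, abs=1e-12)

    def test_overflow_safe(self):
        assert selection_prob("logistic", 1000.0) == 1.0
        assert selection_prob("logistic", -1000.0) == 0.0


class TestUseAvailableLoglik:
    SPEC = ModelSpec("logistic", ["x"])

    @staticmethod
    def eta_for(pi):
        # x chosen so expit(0 + 1*x) == pi under beta = (0, 1)
        return np.log(np.asarray(pi) / (1 - np.asarray(pi)))

    def loglik(self, pi_used, pi_avail):
        data = FakeData(pd.DataFrame({"x": self.eta_for(pi_used)}),
                        pd.DataFrame({"x": self.eta_for(pi_avail)}))
        return use_available_loglik([0.0, 1.0], data, self.SPEC)

    def test_symmetric_case_is_zero(self):
        assert self.loglik([0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_beta_constant_pi_cancels(self):
        data = FakeData(pd.DataFrame({"x": [0.3, -2.0, 5.0]}),
                        pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}))
        assert use_available_loglik([0.0, 0.0], data, self.SPEC) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # 2 used {0.8, 0.4}; availability {0.2, 0.6, 0.4}
        want = np.log(0.8) + np.log(0.4) - 2 * np.log(0.4)
        assert self.loglik([0.8, 0.4], [0.2, 0.6, 0.4]) == pytest.approx(want, abs=1e-10)

    def test_matches_naive_double_loop_oracle(self):
        """Vectorized likelihood equals a brute-force evaluation to 1e-10 on
        20 random small datasets."""
        rng = np.random.default_rng(12)
        for trial in range(20):
            n_u = rng.integers(1, 51)
            n_a = rng.integers(2, 201)
            used = pd.DataFrame({"a": rng.normal(size=n_u), "b": rng.normal(size=n_u)})
            avail = pd.DataFrame({"a": rng.normal(size=n_a), "b": rng.normal(size=n_a)})
            form = "logistic" if trial % 2 else "exponential"
            spec = ModelSpec(form, ["a", "b"])
            beta = rng.normal(scale=0.8, size=spec.k)
            got = use_available_loglik(beta, FakeData(used, avail), spec)

            def pi(row):
                eta = beta[-2] * row["a"] + beta[-1] * row["b"]
                if form == "logistic":
                    eta += beta[0]
                    return expit(eta)
                return np.exp(eta)

            total = 0.0
            for _, row in used.iterrows():
                total += np.log(pi(row))
            s = 0.0
            for _, row in avail.iterrows():
                s += pi(row)
            total -= n_u * np.log(s / n_a)
            assert got == pytest.approx(total, abs=1e-10)

    def test_zero_probability_used_site_gives_neg_inf(self):
        # eta = -800 underflows expit to exactly 0 for the used site
        data = FakeData(pd.DataFrame({"x": [-800.0]}), pd.DataFrame({"x": [0.0]}))
        assert use_available_loglik([0.0, 1.0], data, self.SPEC) == -np.inf


class TestExponentialIntercept:
    def test_constant_shift_leaves_loglik_unchanged(self):
        """Adding any constant to eta of every site leaves the exponential
        use-available log-likelihood unchanged: the intercept is not
        identifiable and is fixed at zero."""
        rng = np.random.default_rng(3)
        spec = ModelSpec("exponential", ["a"])
        used = pd.DataFrame({"a": rng.normal(size=30)})
        avail = pd.DataFrame({"a": rng.normal(size=100)})
        base = use_available_loglik([0.7], FakeData(used, avail), spec)
        for c in (-5.0, 0.3, 12.0):
            # shifting the covariate by c/0.7 adds the constant c to every eta
            shifted = use_available_loglik(
                [0.7], FakeData(used + c / 0.7, avail + c / 0.7), spec)
            assert shifted == pytest.approx(base, abs=1e-10)


class TestFitting:
    @staticmethod
    def toy_dataset(seed=0, n_u=400, n_a=4000, beta=(-1.0, 1.5, -0.8)):
        """Synthetic use-availability rows from a known logistic model via
        importance resampling of availability covariates."""
        rng = np.random.default_rng(seed)
        pool = pd.DataFrame({"a": rng.normal(size=n_a * 20),
                             "b": rng.uniform(-1, 1, size=n_a * 20)})
        eta = beta[0] + beta[1] * pool["a"] + beta[2] * pool["b"]
        pi = expit(eta)
        keep = rng.uniform(size=len(pool)) < pi / pi.max()
        used = pool[keep].head(n_u).reset_index(drop=True)
        avail = pool.sample(n=n_a, random_state=7).reset_index(drop=True)
        df = pd.concat([used.assign(used=1), avail.assign(used=0)], ignore_index=True)
        return df

    def test_recovers_generating_coefficients(self):
        df = self.toy_dataset(seed=5)
        fit = ResourceSelectionModel.from_dataframe(df, "logistic", ["a", "b"]).fit(seed=1)
        assert fit.converged
        for name, truth in zip(["intercept", "a", "b"], (-1.0, 1.5, -0.8)):
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name] + 0.2, name

    def test_refit_is_deterministic(self):
        df = self.toy_dataset(seed=6)
        m = ResourceSelectionModel.from_dataframe(df, "logistic", ["a", "b"])
        f1, f2 = m.fit(seed=3), m.fit(seed=3)
        assert np.array_equal(f1.params.to_numpy(), f2.params.to_numpy())

    def test_constant_covariate_flagged_inestimable(self):
        df = self.toy_dataset(seed=7)
        df["c"] = 2.5
        fit = ResourceSelectionModel.from_dataframe(df, "logistic", ["a", "c"]).fit(seed=1)
        assert any("inestimable" in f for f in fit.flags)
        assert fit.params["c"] == 0.0
        assert np.isnan(fit.bse["c"])
        assert np.isfinite(fit.bse["a"])

    def test_likelihood_at_truth_beats_null(self):
        beta = np.array([-1.0, 1.5, -0.8])
        spec = ModelSpec("logistic", ["a", "b"])
        wins = 0
        for rep in range(20):
            df = self.toy_dataset(seed=100 + rep, n_u=200, n_a=1000)
            m = ResourceSelectionModel(df, spec)
            if m.loglik(beta) >= m.loglik(np.zeros(3)):
                wins += 1
        assert wins >= 19

    def test_separation_flagged(self):
        rng = np.random.default_rng(8)
        used = pd.DataFrame({"g": np.ones(50), "used": 1})
        avail = pd.DataFrame({"g": np.zeros(500), "used": 0})
        df = pd.concat([used, avail], ignore_index=True)
        fit = ResourceSelectionModel.from_dataframe(df, "logistic", ["g"]).fit(seed=1)
        assert ("separation" in fit.flags) or (not fit.converged)

    def test_predictions_in_unit_interval_and_monotone(self):
        df = self.toy_dataset(seed=9)
        fit = ResourceSelectionModel.from_dataframe(df, "logistic", ["a", "b"]).fit(seed=1)
        p = fit.predict()
        assert np.all((p > 0) & (p < 1))
        # raising the covariate with a positive coefficient raises pi
        grid = pd.DataFrame({"a": np.linspace(-2, 2, 9), "b": 0.0})
        pg = fit.predict(grid)
        assert np.all(np.diff(pg) > 0) if fit.params["a"] > 0 else np.all(np.diff(pg) < 0)


class TestStandardErrors:
    def test_quadratic_toy_curvature(self):
        # -l(x) = 0.5 * c * x^2  =>  SE = 1/sqrt(c)
        for c in (0.5, 2.0, 10.0):
            H = fd_hessian(lambda x, c=c: 0.5 * c * float(x[0] ** 2), np.array([0.0]))
            se, _, pd_flag = standard_errors_from_hessian(H)
            assert pd_flag
            assert se[0] == pytest.approx(1.0 / np.sqrt(c), rel=1e-6)

    def test_nonidentified_coordinate_flagged_others_ok(self):
        H = np.diag([4.0, 0.0])  # second coordinate carries no information
        se, _, pd_flag = standard_errors_from_hessian(H)
        assert not pd_flag
        assert se[0] == pytest.approx(0.5, rel=1e-9)
        assert np.isnan(se[1])
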