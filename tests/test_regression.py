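import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from _oracles import (
    exhaustive_best_terms,
    gaussian_aicc,
    prediction_halfwidth,
    solve_normal_equations,
)
from otosr.errors import CollinearTermsError, ValidationError
from otosr.geology import CandidateMatrix, build_candidate_matrix
from otosr.regression import (
    GAConfig,
    INTERCEPT,
    IsoscapeModel,
    fit_ols,
    ga_select,
    predict_interval,
    select_on_sites,
    term_columns,
)


def canon(terms):
    """Canonicalise interaction names (factor order-free) for comparison."""
    return tuple(sorted(":".join(sorted(t.split(":"))) for t in terms))


def matrix_from_frame(frame: pd.DataFrame) -> CandidateMatrix:
    return CandidateMatrix(variables=tuple(frame.columns), frame=frame)


@pytest.fixture()
def small_design(rng):
    frame = pd.DataFrame(
        {
            "a": rng.uniform(0, 1, 6),
            "b": rng.uniform(0, 1, 6),
        },
        index=[f"s{i}" for i in range(6)],
    )
    return frame


class TestFitOls:
    def test_exact_linear_response(self, small_design):
        y = 0.7 + 0.02 * small_design["a"]
        m = fit_ols(y, small_design[["a"]])
        assert m.adjusted_r2 == pytest.approx(1.0)
        assert m.residual_variance == pytest.approx(0.0, abs=1e-28)
        assert m.coefficients["a"] == pytest.approx(0.02)
        assert m.coefficients[INTERCEPT] == pytest.approx(0.7)

    def test_six_point_normal_equations_oracle(self, small_design, rng):
        y = 0.7 + 0.03 * small_design["a"] - 0.01 * small_design["b"]
        y = y + 0.005 * rng.standard_normal(6)
        m = fit_ols(y, small_design)
        X = np.column_stack([np.ones(6), small_design["a"], small_design["b"]])
        beta = solve_normal_equations(X, y.to_numpy())
        assert m.coefficients[INTERCEPT] == pytest.approx(beta[0], abs=1e-10)
        assert m.coefficients["a"] == pytest.approx(beta[1], abs=1e-10)
        assert m.coefficients["b"] == pytest.approx(beta[2], abs=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 40
        frame = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = 0.5 * frame["a"] + rng.standard_normal(n)
        m = fit_ols(y, frame)
        beta = np.array([m.coefficients[INTERCEPT]] +
                        [m.coefficients[t] for t in m.terms])
        X = np.column_stack([np.ones(n), frame.to_numpy()])
        resid = y.to_numpy() - X @ beta
        Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        assert np.all(np.abs(Xs.T @ resid) < 1e-8)

    def test_collinear_terms_named(self, small_design):
        frame = small_design.copy()
        frame["dup"] = frame["a"]
        with pytest.raises(CollinearTermsError) as exc:
            fit_ols(np.linspace(0.70, 0.73, 6), frame)
        assert "dup" in exc.value.terms or "a" in exc.value.terms

    def test_too_few_observations(self, small_design):
        with pytest.raises(ValidationError):
            fit_ols(
                np.linspace(0.70, 0.73, 4),
                small_design.iloc[:4],
            )


class TestAicc:
    def test_matches_arithmetic_oracle(self, small_design, rng):
        y = 0.71 + 0.01 * small_design["a"] + 0.002 * rng.standard_normal(6)
        m = fit_ols(y, small_design[["a"]])
        X = np.column_stack([np.ones(6), small_design["a"]])
        beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        rss = float(((y.to_numpy() - X @ beta) ** 2).sum())
        assert m.aicc == pytest.approx(gaussian_aicc(6, rss, 2), rel=1e-12)

    def test_correction_vanishes_for_large_n(self, rng):
        n = 5000
        frame = pd.DataFrame({"a": rng.uniform(0, 1, n)})
        y = 0.71 + 0.01 * frame["a"] + 0.002 * rng.standard_normal(n)
        m = fit_ols(y, frame)
        k = m.n_parameters
        correction = 2 * k * (k + 1) / (n - k - 1)
        assert correction < 0.01
        assert m.aicc == pytest.approx(
            gaussian_aicc(n, m.residual_variance * (n - 2), 2), rel=1e-9
        )

    def test_noise_term_raises_aicc(self, rng):
        n = 12
        frame = pd.DataFrame(
            {"a": rng.uniform(0, 1, n), "junk": rng.standard_normal(n)}
        )
        y = 0.71 + 0.02 * frame["a"] + 1e-4 * rng.standard_normal(n)
        m1 = fit_ols(y, frame[["a"]])
        m2 = fit_ols(y, frame)
        assert m2.aicc > m1.aicc


class TestSelection:
    def test_single_candidate_returns_it(self, rng):
        frame = pd.DataFrame({"a": rng.uniform(0, 1, 12)})
        y = 0.71 + 0.01 * frame["a"] + 1e-3 * rng.standard_normal(12)
        res = ga_select(
            matrix_from_frame(frame), y, allow_interactions=False,
            validation_fraction=0.0,
        )
        assert res.model.terms == ("a",)

    def test_recovers_true_terms_and_matches_exhaustive(self, rng):
        n = 24
        frame = pd.DataFrame(
            rng.uniform(0, 1, (n, 5)), columns=list("abcde"),
            index=[f"s{i}" for i in range(n)],
        )
        y = 0.71 + 0.03 * frame["b"] - 0.02 * frame["d"]
        y = y + 1e-4 * rng.standard_normal(n)
        res = ga_select(
            matrix_from_frame(frame), y,
            ga_config=GAConfig(seed=5, generations=60),
            validation_fraction=0.0, method="ga",
        )
        pool = list("abcde") + [
            f"{x}:{z}" for i, x in enumerate("abcde") for z in "abcde"[i + 1:]
        ]
        best_terms, best_aicc = exhaustive_best_terms(frame, y, pool, 4)
        assert canon(res.model.terms) == canon(best_terms)
        assert res.model.aicc == pytest.approx(best_aicc, rel=1e-10)
        assert set(best_terms) >= {"b", "d"}

    def test_exhaustive_matches_oracle_on_baseline(self, baseline_sites):
        usable = [s for s in baseline_sites if not s.outlier and not s.predicted]
        matrix = build_candidate_matrix(usable)
        y = [s.sr_ratio for s in usable]
        res = ga_select(matrix, y, validation_fraction=0.0, method="exhaustive")
        pool = list(matrix.variables) + [
            f"{a}:{b}"
            for i, a in enumerate(matrix.variables)
            for b in matrix.variables[i + 1:]
        ]
        best_terms, best_aicc = exhaustive_best_terms(matrix.frame, y, pool, 4)
        assert canon(res.model.terms) == canon(best_terms)
        assert res.model.aicc == pytest.approx(best_aicc, rel=1e-10)

    def test_validation_split_is_reproducible_and_disjoint(self, baseline_sites):
        r1 = select_on_sites(baseline_sites, validation_fraction=1 / 3, seed=11)
        r2 = select_on_sites(baseline_sites, validation_fraction=1 / 3, seed=11)
        assert r1.validation_index == r2.validation_index
        assert len(r1.validation_index) == round(23 / 3)
        assert r1.model.terms == r2.model.terms
        # final model is refit on all 23 usable sites
        assert r1.model.n_obs == 23
        assert r1.search_model.n_obs == 23 - len(r1.validation_index)

    def test_empty_candidates_rejected(self):
        frame = pd.DataFrame(index=["a", "b"])
        with pytest.raises(Exception):
            ga_select(matrix_from_frame(frame), [0.71, 0.72])


class TestPredictInterval:
    def test_halfwidth_matches_closed_form_oracle(self, rng):
        n = 15
        frame = pd.DataFrame(
            {"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)}
        )
        y = 0.71 + 0.02 * frame["a"] - 0.01 * frame["b"]
        y = y + 1e-3 * rng.standard_normal(n)
        m = fit_ols(y, frame)
        new = {"a": 0.3, "b": 0.9}
        pred = predict_interval(m, new)
        X = np.column_stack([np.ones(n), frame["a"], frame["b"]])
        x0 = np.array([1.0, 0.3, 0.9])
        assert pred.interval_halfwidth == pytest.approx(
            prediction_halfwidth(X, y.to_numpy(), x0), rel=1e-12
        )

    def test_agrees_with_statsmodels_observation_interval(self, rng):
        n = 18
        frame = pd.DataFrame({"a": rng.uniform(0, 1, n)})
        y = 0.71 + 0.02 * frame["a"] + 1e-3 * rng.standard_normal(n)
        m = fit_ols(y, frame)
        X = sm.add_constant(frame.to_numpy())
        fit = sm.OLS(y.to_numpy(), X).fit()
        sf = fit.get_prediction([1.0, 0.4]).summary_frame(alpha=0.05)
        pred = predict_interval(m, {"a": 0.4})
        halfwidth = float((sf["obs_ci_upper"] - sf["obs_ci_lower"]).iloc[0]) / 2
        assert pred.interval_halfwidth == pytest.approx(halfwidth, rel=1e-9)
        assert pred.predicted_ratio == pytest.approx(
            float(sf["mean"].iloc[0]), rel=1e-12
        )

    def test_prediction_interval_contains_confidence_interval(self, rng):
        n = 18
        frame = pd.DataFrame({"a": rng.uniform(0, 1, n)})
        y = 0.71 + 0.02 * frame["a"] + 1e-3 * rng.standard_normal(n)
        m = fit_ols(y, frame)
        X = sm.add_constant(frame.to_numpy())
        fit = sm.OLS(y.to_numpy(), X).fit()
        sf = fit.get_prediction([1.0, 0.4]).summary_frame(alpha=0.05)
        ci_halfwidth = float((sf["mean_ci_upper"] - sf["mean_ci_lower"]).iloc[0]) / 2
        assert predict_interval(m, {"a": 0.4}).interval_halfwidth > ci_halfwidth

    def test_noise_free_training_point(self, small_design):
        y = 0.7 + 0.02 * small_design["a"]
        m = fit_ols(y, small_design[["a"]])
        row = {"a": float(small_design["a"].iloc[2])}
        pred = predict_interval(m, row)
        assert pred.predicted_ratio == pytest.approx(float(y.iloc[2]))
        assert pred.interval_halfwidth == pytest.approx(0.0, abs=1e-10)

    def test_halfwidth_grows_with_distance_from_centroid(self, rng):
        n = 30
        frame = pd.DataFrame({"a": rng.uniform(0.4, 0.6, n)})
        y = 0.71 + 0.02 * frame["a"] + 1e-3 * rng.standard_normal(n)
        m = fit_ols(y, frame)
        center = float(frame["a"].mean())
        widths = [
            predict_interval(m, {"a": center + d}).interval_halfwidth
            for d in [0.0, 0.1, 0.2, 0.4, 0.8]
        ]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_missing_term_is_named(self, small_design):
        y = 0.7 + 0.02 * small_design["a"]
        m = fit_ols(y, small_design[["a"]])
        with pytest.raises(ValidationError, match="'a'"):
            predict_interval(m, {"b": 1.0})


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, small_design):
        y = 0.7 + 0.02 * small_design["a"] - 0.005 * small_design["b"]
        m = fit_ols(y, term_columns(small_design, ["a", "a:b"]))
        again = IsoscapeModel.from_json(m.to_json())
        new = {"a": 0.4, "b": 0.2}
        assert again.predict(new) == pytest.approx(m.predict(new), rel=1e-15)
        p1 = predict_interval(m, new)
        p2 = predict_interval(again, new)
        assert p1.interval_halfwidth == pytest.approx(p2.interval_halfwidth)


class TestParameterRecovery:
    def test_coefficients_within_three_se_of_truth(self, rng):
        """With Gaussian noise the fitted coefficients should sit within
        3 standard errors of the generating values in ~99% of replicates."""
        n = 30
        truth = {"a": 0.025, "b": -0.012}
        hits = total = 0
        for _ in range(200):
            frame = pd.DataFrame(
                {"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)}
            )
            y = 0.71 + truth["a"] * frame["a"] + truth["b"] * frame["b"]
            y = y + 0.002 * rng.standard_normal(n)
            m = fit_ols(y, frame)
            cov = m.residual_variance * m.design_moment_inverse
            se = np.sqrt(np.diag(cov))
            for i, t in enumerate(m.terms, start=1):
                total += 1
                if abs(m.coefficients[t] - truth[t]) <= 3 * se[i]:
                    hits += 1
        assert hits / total >= 0.95
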