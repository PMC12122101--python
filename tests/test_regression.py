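"""Oracle-backed tests of the OLS / VIF / AICc / averaging machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import (
    OLSInfluence,
    variance_inflation_factor,
)

from chumrun import regression as reg
from conftest import toy_regression_data


class TestOlsFit:
    def test_matches_statsmodels(self, rng):
        y, Z = toy_regression_data(rng)
        fit = reg.ols_fit(y, Z)
        sm_fit = sm.OLS(y, sm.add_constant(Z)).fit()
        np.testing.assert_allclose(fit.beta, sm_fit.params.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(fit.se, sm_fit.bse.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(fit.r2, sm_fit.rsquared, atol=1e-10)
        np.testing.assert_allclose(fit.adj_r2, sm_fit.rsquared_adj, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rng):
        y, Z = toy_regression_data(rng)
        fit = reg.ols_fit(y, Z)
        X = np.column_stack([np.ones(len(y)), Z.to_numpy()])
        beta = np.linalg.pinv(X) @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.pinv(X.T @ X)))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        np.testing.assert_allclose(fit.se, se, atol=1e-8)

    def test_aicc_formula(self, rng):
        y, Z = toy_regression_data(rng, s=2)
        fit = reg.ols_fit(y, Z)
        n, k = fit.n, fit.p + 1
        expected = n * math.log(fit.rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected)

    def test_intercept_only_is_mean(self, rng):
        y = rng.standard_normal(15)
        fit = reg.ols_fit(y, pd.DataFrame(index=range(15)))
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_exact_linear_data(self):
        Z = pd.DataFrame({"z": np.arange(10.0)})
        y = 2.0 + 3.0 * Z["z"].to_numpy()
        fit = reg.ols_fit(y, Z)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)
        assert np.isfinite(fit.aicc)

    def test_rank_deficiency_names_columns(self, rng):
        z = rng.standard_normal(12)
        Z = pd.DataFrame({"a": z, "b": 2 * z})
        with pytest.raises(ValueError, match="collinear"):
            reg.ols_fit(rng.standard_normal(12), Z)


class TestVif:
    def test_orthogonal_columns_all_one(self, rng):
        n = 12
        M = rng.standard_normal((n, 3))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))   # mutually orthogonal, sum 0
        Z = pd.DataFrame(Q, columns=list("abc"))
        vifs = reg.vif_values(Z)
        kept, removed = reg.vif_screen(Z)
        assert (vifs < 1.0 + 1e-8).all()
        assert removed == []

    def test_matches_statsmodels_oracle(self, rng):
        _, Z = toy_regression_data(rng, s=4)
        Z["z5"] = Z["z1"] + rng.standard_normal(len(Z)) * 0.3
        vifs = reg.vif_values(Z)
        X = sm.add_constant(Z).to_numpy()
        for j, name in enumerate(Z.columns):
            oracle = variance_inflation_factor(X, j + 1)
            assert vifs[name] == pytest.approx(oracle, rel=1e-8)

    def test_duplicated_column_removed_first(self, rng):
        z = rng.standard_normal(15)
        Z = pd.DataFrame({"a": z, "b": z, "c": rng.standard_normal(15)})
        kept, removed = reg.vif_screen(Z)
        assert removed[0][0] == "a"  # lexicographic tie-break at VIF=inf
        assert math.isinf(removed[0][1])
        assert (reg.vif_values(kept) < 3.0).all()

    def test_known_vif_value(self, rng):
        # x2 = x1 + e scaled so that R^2 of x1 on x2 is exactly 0.8
        n = 400
        x1 = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x1 = (x1 - x1.mean()) / x1.std()
        e = e - e.mean()
        e -= x1 * (x1 @ e) / (x1 @ x1)   # make e exactly orthogonal to x1
        e = e / e.std()
        x2 = x1 + e / 2.0                # R^2 = 1/(1+1/4) = 0.8
        vifs = reg.vif_values(pd.DataFrame({"x1": x1, "x2": x2}))
        assert vifs["x1"] == pytest.approx(1.0 / (1.0 - 0.8), rel=1e-9)

    def test_screen_terminates_below_threshold(self, rng):
        n = 30
        base = rng.standard_normal((n, 2))
        Z = pd.DataFrame({
            "a": base[:, 0],
            "b": base[:, 0] * 0.9 + rng.standard_normal(n) * 0.2,
            "c": base[:, 1],
            "d": base[:, 1] * 0.9 + rng.standard_normal(n) * 0.2,
        })
        kept, removed = reg.vif_screen(Z, threshold=3.0)
        assert (reg.vif_values(kept) < 3.0).all()
        assert set(kept.columns) | {r[0] for r in removed} == set(Z.columns)


class TestAllSubsets:
    def test_single_covariate_choice(self, rng):
        y, Z = toy_regression_data(rng, s=1)
        ranked = reg.all_subsets_select(y, Z)
        assert {m.names for m in ranked} == {(), ("z1",)}
        assert ranked[0].aicc <= ranked[1].aicc

    def test_matches_bruteforce_enumeration(self, rng):
        """Ranking of all 2^3 subsets equals an independent statsmodels
        enumeration with the same AICc convention."""
        y, Z = toy_regression_data(rng, s=3)
        ranked = reg.all_subsets_select(y, Z)
        oracle = []
        n = len(y)
        for r in range(4):
            for combo in itertools.combinations(Z.columns, r):
                X = sm.add_constant(Z[list(combo)]) if combo else \
                    pd.DataFrame({"const": np.ones(n)})
                res = sm.OLS(y, X).fit()
                k = len(combo) + 2
                aicc = (n * math.log(res.ssr / n) + 2 * k
                        + 2 * k * (k + 1) / (n - k - 1))
                oracle.append((aicc, combo))
        oracle.sort(key=lambda t: (t[0], len(t[1]), t[1]))
        for mine, (aicc, combo) in zip(ranked, oracle):
            assert mine.names == combo
            assert mine.aicc == pytest.approx(aicc, abs=1e-8)

    def test_true_support_recovered_with_strong_signal(self):
        """With two strong true covariates among 8 candidates the best model
        contains the true support in at least 80% of seeded replicates."""
        rng = np.random.default_rng(77)
        n, hits, reps = 22, 0, 50
        for _ in range(reps):
            Z = pd.DataFrame(
                rng.standard_normal((n, 8)),
                columns=[f"z{i+1}" for i in range(8)],
            )
            y = 0.5 + 1.5 * Z["z1"].to_numpy() - 1.5 * Z["z2"].to_numpy() \
                + rng.standard_normal(n) * 0.3
            best = reg.all_subsets_select(y, Z)[0]
            hits += {"z1", "z2"} <= set(best.names)
        assert hits / reps >= 0.8


class TestSubsetModelComparison:
    def test_parsimony_tie_break(self, rng):
        """A combination tie resolves toward fewer subset-model groups."""
        n = 24
        z = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        y = 1.0 + z["a"].to_numpy() * 2.0 + rng.standard_normal(n) * 0.1
        sel = reg.compare_subset_models(
            y, z, groups={"g1": ["a"], "g2": ["b"]},
        )
        # {g1} and {g1,g2} share the same best submodel (a); g1 must win
        assert sel.winner.groups == ("g1",)
        assert sel.best_model.names == ("a",)

    def test_winner_has_minimal_aicc(self, rng):
        y, Z = toy_regression_data(rng, s=4)
        groups = {"g1": ["z1", "z2"], "g2": ["z3"], "g3": ["z4"]}
        sel = reg.compare_subset_models(y, Z, groups)
        mins = [c.best.aicc for c in sel.combinations]
        assert sel.best_model.aicc == pytest.approx(min(mins))
        assert len(sel.combinations) == 7  # all non-empty group combinations

    def test_groups_must_be_disjoint(self, rng):
        y, Z = toy_regression_data(rng, s=2)
        with pytest.raises(ValueError, match="disjoint"):
            reg.compare_subset_models(y, Z, {"a": ["z1"], "b": ["z1", "z2"]})


class TestModelAverage:
    def _ranked(self, items):
        out = []
        for names, aicc_val, coefs in items:
            fit = reg.FitResult(
                names=names, beta=np.array(coefs), se=np.ones(len(coefs)),
                sigma2=1.0, n=20, p=len(coefs), k=len(coefs) + 1, rss=1.0,
                aicc=aicc_val, r2=0.5, adj_r2=0.5, fitted=None, residuals=None,
                leverage=None, xtx_inv=None,
            )
            out.append(reg.RankedModel(names=names, aicc=aicc_val, fit=fit))
        return out

    def test_single_model(self):
        ranked = self._ranked([(("a",), 10.0, [1.0, 2.0])])
        table, weights = reg.model_average(ranked)
        assert table.loc["a", "estimate"] == pytest.approx(2.0)
        assert weights.sum() == pytest.approx(1.0)

    def test_equal_aicc_split(self):
        ranked = self._ranked([
            (("a",), 10.0, [0.0, 2.0]),
            (("a", "b"), 10.0, [0.0, 4.0, 1.0]),
        ])
        table, weights = reg.model_average(ranked)
        np.testing.assert_allclose(weights.to_numpy(), [0.5, 0.5])
        assert table.loc["a", "estimate"] == pytest.approx(3.0)
        # conditional: b averaged only over the model containing it
        assert table.loc["b", "estimate"] == pytest.approx(1.0)
        assert table.loc["b", "weight"] == pytest.approx(0.5)

    def test_hand_computed_weights(self):
        # AICc 100 vs 101: weights 1/(1+e^-0.5), e^-0.5/(1+e^-0.5)
        ranked = self._ranked([
            (("a",), 100.0, [0.0, 1.0]),
            (("b",), 101.0, [0.0, 3.0]),
        ])
        table, weights = reg.model_average(ranked)
        w2 = math.exp(-0.5) / (1 + math.exp(-0.5))
        np.testing.assert_allclose(weights.to_numpy(), [1 - w2, w2], atol=1e-9)
        assert abs(w2 - 0.378) < 1e-3

    def test_threshold_excludes_distant_models(self):
        ranked = self._ranked([
            (("a",), 10.0, [0.0, 1.0]),
            (("b",), 13.0, [0.0, 9.0]),
        ])
        table, weights = reg.model_average(ranked, delta=2.0)
        assert "b" not in table.index
        assert len(weights) == 1


class TestEffectSizes:
    def test_zero_coefficient(self):
        tab = reg.effect_sizes({"x": 0.0}, {"x": 0.1})
        assert tab.loc["x", "effect_size"] == pytest.approx(1.0)
        assert tab.loc["x", "practical_pct"] == pytest.approx(0.0)
        assert tab.loc["x", "ci_lower"] < 1.0 < tab.loc["x", "ci_upper"]

    def test_monotone_in_beta_and_ci_contains_point(self, rng):
        betas = np.sort(rng.standard_normal(9))
        tab = reg.effect_sizes(
            pd.Series(betas, index=[f"b{i}" for i in range(9)]),
            pd.Series(0.2, index=[f"b{i}" for i in range(9)]),
        )
        assert tab["effect_size"].is_monotonic_increasing
        assert ((tab["ci_lower"] <= tab["effect_size"])
                & (tab["effect_size"] <= tab["ci_upper"])).all()


class TestPrediction:
    def test_matches_statsmodels_intervals(self, rng):
        y, Z = toy_regression_data(rng, s=2)
        fit = reg.ols_fit(y, Z)
        pred = reg.predict_with_intervals(fit, Z)
        sm_fit = sm.OLS(y, sm.add_constant(Z)).fit()
        frame = sm_fit.get_prediction(sm.add_constant(Z)).summary_frame(alpha=0.05)
        np.testing.assert_allclose(
            np.log(pred["pi_lower"]), frame["obs_ci_lower"], atol=1e-8)
        np.testing.assert_allclose(
            np.log(pred["pi_upper"]), frame["obs_ci_upper"], atol=1e-8)

    def test_centroid_prediction_is_mean(self, rng):
        y, Z = toy_regression_data(rng, s=2)
        fit = reg.ols_fit(y, Z)
        centroid = Z.mean().to_frame().T
        pred = reg.predict_with_intervals(fit, centroid)
        assert pred["pred_log"].iloc[0] == pytest.approx(y.mean())

    def test_interval_width_grows_with_distance(self, rng):
        y, Z = toy_regression_data(rng, s=1)
        fit = reg.ols_fit(y, Z)
        c = Z["z1"].mean()
        steps = pd.DataFrame({"z1": c + np.array([0.0, 0.5, 1.0, 2.0])})
        pred = reg.predict_with_intervals(fit, steps)
        widths = np.log(pred["pi_upper"]) - np.log(pred["pi_lower"])
        assert np.all(np.diff(widths) >= -1e-12)


class TestDiagnostics:
    def test_studentized_matches_statsmodels_loo(self, rng):
        y, Z = toy_regression_data(rng, s=2)
        fit = reg.ols_fit(y, Z)
        mine = reg.studentized_residuals(fit)
        oracle = OLSInfluence(
            sm.OLS(y, sm.add_constant(Z)).fit()
        ).resid_studentized_external
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_perfect_fit_skipped(self):
        Z = pd.DataFrame({"z": np.arange(12.0)})
        y = 1.0 + 2.0 * Z["z"].to_numpy()
        diag = reg.residual_diagnostics(reg.ols_fit(y, Z), rng=0)
        assert diag.skipped
        assert "perfect" in diag.notice

    def test_normal_data_mostly_inside_envelope(self):
        rng = np.random.default_rng(3)
        good = 0
        reps = 100
        for _ in range(reps):
            y, Z = toy_regression_data(rng, s=2)
            diag = reg.residual_diagnostics(reg.ols_fit(y, Z), rng=rng)
            good += diag.fraction_inside >= 0.9
        assert good / reps >= 0.95
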