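"""Orthogonal bases, mixed-model fitting, Wald/LRT inference and the PCA
meta-parameter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from toolplast import lmm
from toolplast import simulate as sim


def gram_schmidt_basis(x, degree):
    """Brute-force oracle: Gram-Schmidt on {1, x, x^2, ...}, constant dropped,
    columns normalised to unit length."""
    x = np.asarray(x, dtype=float)
    raw = np.column_stack([x**d for d in range(degree + 1)])
    q = []
    for col in raw.T:
        v = col.copy()
        for u in q:
            v = v - (v @ u) * u
        q.append(v / np.linalg.norm(v))
    return np.column_stack(q[1:])


class TestOrthogonalBasis:
    def test_degree_one_closed_form(self):
        b = lmm.orthogonal_poly_basis([1, 2, 3], 1)
        np.testing.assert_allclose(
            b.columns.ravel(), [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)], atol=1e-12)

    def test_degree_two_closed_form(self):
        b = lmm.orthogonal_poly_basis([1, 2, 3], 2)
        np.testing.assert_allclose(
            b.columns[:, 1], np.array([1, -2, 1]) / np.sqrt(6), atol=1e-12)

    @given(st.lists(st.integers(5, 20), min_size=8, max_size=40).filter(
        lambda xs: len(set(xs)) >= 3))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_gram_schmidt_oracle(self, xs):
        basis = lmm.orthogonal_poly_basis(xs, 2)
        oracle = gram_schmidt_basis(xs, 2)
        for j in range(2):
            col, ref = basis.columns[:, j], oracle[:, j]
            sign = np.sign(col @ ref)
            np.testing.assert_allclose(col, sign * ref, atol=1e-10)

    def test_orthonormality_and_out_of_sample_evaluation(self):
        rng = np.random.default_rng(3)
        x = rng.integers(5, 21, size=60).astype(float)
        basis = lmm.orthogonal_poly_basis(x, 2)
        gram = basis.columns.T @ basis.columns
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)
        assert np.allclose(basis.columns.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis.evaluate(x), basis.columns, atol=1e-10)
        grid = basis.evaluate(np.linspace(5, 20, 7))
        assert grid.shape == (7, 2) and np.all(np.isfinite(grid))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            lmm.orthogonal_poly_basis([4.0, 4.0, 7.0], 2)


def simulate_frame(n_subj=30, n_trials=6, seed=0, **spec_kwargs):
    defaults = dict(baseline=100.0, session_main=10.0, puberty_curve=(0.0, 1.0),
                    interaction_curve=(0.0, -1.0), subject_sd=8.0,
                    residual_sd=15.0)
    defaults.update(spec_kwargs)
    cohort = sim.generate_cohort(n_subj, seed=seed)
    table = sim.generate_trial_parameters(cohort, {"y": sim.EffectSpec(**defaults)},
                                          n_trials=n_trials, seed=seed + 1)
    return sim.pivot_trials(table)


class TestFitLMM:
    def test_zero_subject_variance_matches_ols(self):
        wide = simulate_frame(seed=5, subject_sd=0.0)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        X, *_ = lmm._build_design(wide, "session", ("PRE", "POST"), "puberty", 2, None)
        beta_ols, *_ = np.linalg.lstsq(X, wide["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params, beta_ols, atol=1e-5)
        assert fit.subject_var < 0.05 * fit.resid_var

    def test_balanced_condition_coefficient_is_mean_difference(self):
        """Under -1/2 / +1/2 coding with a balanced design, the condition
        coefficient equals the difference of condition means."""
        wide = simulate_frame(seed=7)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        diff = (wide.loc[wide.session == "POST", "y"].mean()
                - wide.loc[wide.session == "PRE", "y"].mean())
        assert fit.params[1] == pytest.approx(diff, abs=1e-6)

    def test_missing_condition_level_rejected(self):
        wide = simulate_frame(seed=7)
        with pytest.raises(ValueError, match="absent"):
            lmm.fit_lmm(wide[wide.session == "PRE"], "y", degree=2)

    def test_fit_serialises_to_json(self):
        import json
        wide = simulate_frame(seed=3)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        payload = json.loads(json.dumps(fit.to_dict()))
        assert payload["outcome"] == "y"
        assert set(payload["coefficients"]) == set(fit.column_names)
        assert payload["basis"]["degree"] == 2
        assert payload["n_subjects"] == 30

    def test_constant_outcome_rejected(self):
        wide = simulate_frame(seed=7)
        wide["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            lmm.fit_lmm(wide, "y")

    def test_variance_components_recovered(self):
        wide = simulate_frame(n_subj=60, n_trials=12, seed=13,
                              subject_sd=20.0, residual_sd=10.0)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        assert np.sqrt(fit.subject_var) == pytest.approx(20.0, rel=0.30)
        assert np.sqrt(fit.resid_var) == pytest.approx(10.0, rel=0.10)

    def test_parameter_recovery_difference_curve(self):
        """Across replicate cohorts, the fitted POST-PRE difference curve is
        nearly unbiased and its model SE tracks the replicate scatter."""
        spec = sim.EffectSpec(baseline=100.0, session_main=0.0,
                              puberty_curve=(0.0, 1.0),
                              interaction_curve=(0.0, -2.0), subject_sd=8.0,
                              residual_sd=15.0, target_crossing=16.0)
        probes = np.array([6.0, 12.0, 19.0])
        diffs, ses = [], []
        for r in range(40):
            cohort = sim.generate_cohort(30, seed=100 + r)
            table = sim.generate_trial_parameters(cohort, {"y": spec}, 6,
                                                  seed=200 + r)
            fit = lmm.fit_lmm(sim.pivot_trials(table), "y", degree=2)
            rows = fit.design_row("POST", probes) - fit.design_row("PRE", probes)
            diffs.append(rows @ fit.params)
            ses.append(np.sqrt(np.einsum("ij,jk,ik->i", rows, fit.cov_params, rows)))
        diffs, ses = np.array(diffs), np.array(ses)
        truth = spec.difference(probes)
        scale = np.ptp(spec.difference(np.array([5.0, 20.0])))
        np.testing.assert_allclose(diffs.mean(axis=0), truth,
                                   atol=0.05 * scale)
        np.testing.assert_allclose(ses.mean(axis=0), diffs.std(axis=0),
                                   rtol=0.30)


class TestWaldType3:
    def test_single_coefficient_chi2_identity(self):
        """For 1-df terms, chi2 equals (beta / SE)^2 exactly."""
        wide = simulate_frame(seed=9)
        fit = lmm.fit_lmm(wide, "y", degree=1)
        table = lmm.wald_type3(fit).set_index("term")
        se = np.sqrt(np.diag(fit.cov_params))
        for term, idx in fit.term_blocks.items():
            assert len(idx) == 1
            z2 = (fit.params[idx[0]] / se[idx[0]]) ** 2
            assert table.loc[term, "chi2"] == pytest.approx(z2, rel=1e-10)

    def test_strong_interaction_detected(self):
        wide = simulate_frame(seed=15, interaction_curve=(0.0, -5.0),
                              residual_sd=10.0)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        table = lmm.wald_type3(fit).set_index("term")
        assert table.loc["interaction", "p"] < 1e-6

    def test_basis_invariance_of_fitted_values_and_type3(self):
        """Fitted values and the interaction Type III p-value agree whether
        the quadratic term uses the orthogonal basis or raw centered powers."""
        import statsmodels.api as sm
        import warnings

        wide = simulate_frame(seed=23, n_subj=24, n_trials=4)
        fit = lmm.fit_lmm(wide, "y", degree=2)
        s = wide["session"].map({"PRE": -0.5, "POST": 0.5}).to_numpy()
        xc = wide["puberty"].to_numpy(float)
        xc = xc - xc.mean()
        X_raw = np.column_stack([np.ones_like(xc), s, xc, xc**2, s * xc, s * xc**2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = sm.MixedLM(wide["y"].to_numpy(), X_raw,
                             groups=wide["subject_id"].to_numpy()).fit(reml=True)
        X_orth, *_ = lmm._build_design(wide, "session", ("PRE", "POST"),
                                       "puberty", 2, None)
        np.testing.assert_allclose(X_orth @ fit.params, X_raw @ raw.fe_params,
                                   atol=1e-5)
        b = raw.fe_params[4:6]
        V = np.asarray(raw.cov_params())[4:6, 4:6]
        chi2_raw = float(b @ np.linalg.solve(V, b))
        p_raw = stats.chi2.sf(chi2_raw, 2)
        table = lmm.wald_type3(fit).set_index("term")
        assert table.loc["interaction", "p"] == pytest.approx(p_raw, abs=1e-6)


class TestLRT:
    def test_statistic_nonnegative_and_selection(self):
        wide = simulate_frame(seed=31)
        out = lmm.lrt_poly_vs_linear(wide, "y")
        assert out["chi2"] >= 0.0 and out["df"] == 2
        assert out["llf_quadratic"] >= out["llf_linear"] - 1e-6
        assert out["selected"] in ("linear", "quadratic")

    def test_strong_quadratic_interaction_selected(self):
        wide = simulate_frame(seed=37, n_subj=40,
                              interaction_curve=(-150.0, 24.0, -0.96),
                              residual_sd=10.0)
        out = lmm.lrt_poly_vs_linear(wide, "y")
        assert out["selected"] == "quadratic" and out["p"] < 1e-4


class TestPCAMeta:
    def test_rank_one_table(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        wide = pd.DataFrame({f"p{i}": (i + 1.0) * z + i for i in range(9)})
        meta = lmm.pca_meta(wide, [f"p{i}" for i in range(9)], "p0")
        assert meta.explained_variance_fraction == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.abs(meta.loadings), 1 / 3, atol=1e-10)

    def test_two_variable_closed_form(self):
        """First-component fraction of a 2-variable PCA is (1 + |rho|) / 2."""
        rng = np.random.default_rng(1)
        n = 400
        a = rng.standard_normal(n)
        a = a - a.mean()
        b = rng.standard_normal(n)
        b = b - b.mean()
        b = b - (b @ a) / (a @ a) * a          # exactly decorrelate
        rho = 0.6
        y = rho / np.std(a) * a + np.sqrt(1 - rho**2) / np.std(b) * b
        wide = pd.DataFrame({"u": a, "v": y})
        meta = lmm.pca_meta(wide, ["u", "v"], "u")
        empirical_rho = np.corrcoef(a, y)[0, 1]
        assert meta.explained_variance_fraction == pytest.approx(
            (1 + abs(empirical_rho)) / 2, abs=1e-10)
        assert empirical_rho == pytest.approx(0.6, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        wide = pd.DataFrame(rng.standard_normal((80, 9)) @ rng.standard_normal((9, 9)),
                            columns=[f"p{i}" for i in range(9)])
        names = list(wide.columns)
        meta = lmm.pca_meta(wide, names, "p0")
        z = (wide - wide.mean()) / wide.std(ddof=1)
        eigvals, eigvecs = np.linalg.eigh(np.corrcoef(z.to_numpy(), rowvar=False))
        v = eigvecs[:, -1]
        v = v if v[0] > 0 else -v
        np.testing.assert_allclose(meta.loadings.to_numpy(), v, atol=1e-8)
        np.testing.assert_allclose(meta.scores.to_numpy(), z.to_numpy() @ v,
                                   atol=1e-8)
        assert meta.explained_variance_fraction == pytest.approx(
            eigvals[-1] / 9, abs=1e-10)

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        wide.iloc[[3, 8], 1] = np.nan
        meta = lmm.pca_meta(wide, ["a", "b", "c"], "a")
        assert meta.n_dropped == 2 and len(meta.scores) == 28

    def test_constant_parameter_rejected(self):
        wide = pd.DataFrame({"a": np.arange(20.0), "b": np.ones(20)})
        with pytest.raises(ValueError, match="constant"):
            lmm.pca_meta(wide, ["a", "b"], "a")


class TestImitation:
    def test_exact_linear_selects_linear(self):
        puberty = np.arange(5, 21, dtype=float)
        scores = 40.0 + 1.2 * puberty
        out = lmm.imitation_regression(scores, puberty)
        assert out["selected"] == "linear"
        assert out["quadratic_fit"]["quadratic_coef"] == pytest.approx(0.0, abs=1e-8)

    def test_pure_parabola_selects_quadratic(self):
        puberty = np.arange(5, 21, dtype=float)
        scores = 70.0 - 0.3 * (puberty - 12.5) ** 2
        out = lmm.imitation_regression(scores, puberty)
        assert out["selected"] == "quadratic"

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="72"):
            lmm.imitation_regression([10.0, 80.0, 20.0, 30.0], [5.0, 8.0, 12.0, 16.0])

    def test_linear_truth_with_noise_mostly_selects_linear(self):
        """At study-like n, the linear model wins in >= 90% of simulations."""
        wins = 0
        for r in range(50):
            cohort = sim.generate_cohort(90, seed=400 + r)
            df = sim.generate_imitation_scores(cohort, seed=500 + r)
            out = lmm.imitation_regression(df["score"], df["puberty"])
            wins += out["selected"] == "linear"
        assert wins >= 45
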