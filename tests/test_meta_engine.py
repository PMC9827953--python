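import subprocess
import textwrap

import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from iezmeta.meta_design import ModeratorSpec, RandomEffectsSpec, build_design
from iezmeta.meta_engine import (aicc, egger_test, fit_model,
                                 profile_component, q_e, q_m, r2_nakagawa,
                                 reml_fit, typical_sampling_variance,
                                 variance_proportions)


def _restricted_m2ll(sigma2, y, V, X):
    """Independent textbook restricted -2 log-likelihood, one component."""
    n, p = X.shape
    M = V + sigma2 * np.eye(n)
    Mi = np.linalg.inv(M)
    A = X.T @ Mi @ X
    beta = np.linalg.solve(A, X.T @ Mi @ y)
    r = y - X @ beta
    return ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(M)[1]
            + np.linalg.slogdet(A)[1] + r @ Mi @ r)


class TestRemlClosedForms:
    def test_single_observation(self):
        m = reml_fit(np.array([0.7]), np.array([[0.09]]), np.ones((1, 1)),
                     [np.arange(1)], fixed_sigma2=np.array([0.0]))
        assert m.beta[0] == pytest.approx(0.7)
        assert m.se[0] == pytest.approx(0.3)

    def test_inverse_variance_weighted_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 12)
        v = rng.uniform(0.3, 2.0, 12)
        m = reml_fit(y, np.diag(v), np.ones((12, 1)), [np.arange(12)],
                     fixed_sigma2=np.array([0.0]))
        w = 1 / v
        assert m.beta[0] == pytest.approx(np.sum(w * y) / np.sum(w),
                                          rel=1e-12)
        assert m.se[0] == pytest.approx(np.sqrt(1 / np.sum(w)), rel=1e-12)

    def test_matches_grid_maximization(self):
        # one-component REML vs direct 1-D minimization of the
        # independent restricted -2ll
        rng = np.random.default_rng(5)
        for rep in range(5):
            v = rng.uniform(0.2, 1.0, 20)
            y = rng.normal(0.3, np.sqrt(v + 0.5))
            V, X = np.diag(v), np.ones((20, 1))
            m = reml_fit(y, V, X, [np.arange(20)])
            direct = scipy.optimize.minimize_scalar(
                _restricted_m2ll, bounds=(1e-8, 10), method="bounded",
                args=(y, V, X), options={"xatol": 1e-10})
            assert m.sigma2[0] == pytest.approx(direct.x, abs=1e-3)
            assert -2 * m.loglik_restricted == pytest.approx(direct.fun,
                                                             abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 25
        v = rng.uniform(0.3, 1.5, n)
        y = rng.normal(0.1, np.sqrt(v + 0.3))
        g = rng.integers(0, 5, n)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        m1 = reml_fit(y, np.diag(v), X, [np.arange(n), g])
        perm = rng.permutation(n)
        m2 = reml_fit(y[perm], np.diag(v[perm]), X[perm],
                      [np.arange(n), g[perm]])
        np.testing.assert_allclose(m2.beta, m1.beta, rtol=1e-6)
        np.testing.assert_allclose(m2.sigma2, m1.sigma2, rtol=1e-4,
                                   atol=1e-8)
        assert m2.loglik_restricted == pytest.approx(m1.loglik_restricted,
                                                     abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        y = np.zeros(5)
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_fit(y, np.eye(5), X, [np.arange(5)])

    def test_zero_variance_rows_floored_with_warning(self):
        V = np.diag([1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="floored"):
            m = reml_fit(np.array([0.1, 0.2, 0.3]), V, np.ones((3, 1)),
                         [np.arange(3)], fixed_sigma2=np.array([0.0]))
        assert np.isfinite(m.beta[0])


class TestQE:
    def test_perfect_fit_zero(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        y = X @ np.array([1.0, 2.0])
        stat, df, p = q_e(y, np.eye(4), X)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_hand_arithmetic(self):
        stat, df, p = q_e(np.array([1.0, -1.0]), np.eye(2), np.ones((2, 1)))
        assert stat == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(scipy.stats.chi2.sf(2.0, 1))

    def test_singular_v_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            q_e(np.array([1.0, 2.0]), np.zeros((2, 2)), np.ones((2, 1)))


class TestQM:
    def _fitted(self, seed=3, n=40):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.3, 1.0, n)
        x = rng.normal(size=n)
        y = rng.normal(0.2 + 0.8 * x, np.sqrt(v + 0.2))
        X = np.column_stack([np.ones(n), x])
        m = reml_fit(y, np.diag(v), X, [np.arange(n)],
                     beta_labels=["intercept", "distance"])
        m.spec = ModeratorSpec(["distance"])
        return m

    def test_single_coefficient_equals_squared_wald(self):
        m = self._fitted()
        stat, df, p = q_m(m, ["distance"], drop_interactions=False)
        assert df == 1
        assert stat == pytest.approx((m.beta[1] / m.se[1]) ** 2, rel=1e-10)
        assert p == pytest.approx(m.pvalues[1], rel=1e-8)

    def test_df_equals_number_of_tested_coefficients(self, small_effect_set):
        m = fit_model(small_effect_set,
                      ModeratorSpec(["distance", "habitat"]),
                      RandomEffectsSpec(), "reptile", multistart=False,
                      with_stats=False)
        _, df, _ = q_m(m, ["distance", "habitat"])
        assert df == 2

    def test_main_effect_refit_drops_interactions(self, small_effect_set):
        m = fit_model(small_effect_set,
                      ModeratorSpec(["distance", "habitat",
                                     "distance:habitat"]),
                      RandomEffectsSpec(), "reptile", multistart=False,
                      with_stats=False)
        # habitat main effect tested after dropping distance:habitat
        stat_drop, df_drop, _ = q_m(m, ["habitat"])
        assert df_drop == 1
        sub = fit_model(small_effect_set,
                        ModeratorSpec(["distance", "habitat"]),
                        RandomEffectsSpec(), "reptile", multistart=False,
                        with_stats=False)
        j = sub.beta_labels.index("habitat")
        assert stat_drop == pytest.approx((sub.beta[j] / sub.se[j]) ** 2,
                                          rel=1e-6)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            q_m(self._fitted(), [])


class TestAicc:
    def test_formula_arithmetic(self):
        m = self._model(loglik=-50.0, k=1, n=100)
        assert aicc(m) == pytest.approx(102 + 4 / 98)

    def test_difference_from_aic_is_exact_penalty(self):
        m = self._model(loglik=-31.7, k=4, n=60)
        aic = -2 * m.loglik_full + 2 * m.n_params
        assert aicc(m) - aic == pytest.approx(
            2 * 4 * 5 / (60 - 4 - 1), rel=1e-12)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(self._model(loglik=-1.0, k=5, n=6))

    @staticmethod
    def _model(loglik, k, n):
        from iezmeta.meta_engine import FittedMetaModel
        return FittedMetaModel(
            beta=np.zeros(1), beta_labels=["intercept"],
            beta_cov=np.eye(1), ci_low=np.zeros(1), ci_high=np.zeros(1),
            pvalues=np.ones(1), sigma2=np.zeros(1),
            sigma2_labels=("observation",), loglik_restricted=loglik,
            loglik_full=loglik, converged=True, n_obs=n, n_params=k)


class TestR2AndProportions:
    def test_null_model_marginal_zero(self, small_effect_set):
        m = fit_model(small_effect_set, ModeratorSpec(["intercept"]),
                      RandomEffectsSpec(), "reptile", multistart=False,
                      with_stats=False)
        r2m, r2c = r2_nakagawa(m)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert 0 <= r2c <= 1

    def test_forced_half_split(self):
        # all sigma at 0 and var(fitted) == s^2 -> R2m = R2c = 0.5
        n = 50
        x = np.linspace(-1, 1, n)
        v = np.full(n, 0.7)
        s2 = typical_sampling_variance(np.diag(v))
        rng = np.random.default_rng(0)
        y = x + rng.normal(0, 0.01, n)
        X = np.column_stack([np.ones(n), x])
        m = reml_fit(y, np.diag(v), X, [np.arange(n)],
                     fixed_sigma2=np.array([0.0]))
        fitted = X @ m.beta
        sf2 = np.var(fitted, ddof=1)
        r2m, r2c = r2_nakagawa(m)
        assert r2m == pytest.approx(sf2 / (sf2 + s2), rel=1e-10)
        assert r2c == pytest.approx(r2m, rel=1e-10)

    def test_proportions_match_independent_arithmetic(self, small_effect_set):
        m = fit_model(small_effect_set, ModeratorSpec(["distance"]),
                      RandomEffectsSpec(), "reptile", multistart=False,
                      with_stats=False)
        props = variance_proportions(m)
        s2 = typical_sampling_variance(m.V)
        denom = m.sigma2.sum() + s2
        for lab, val in zip(m.sigma2_labels, m.sigma2):
            assert props[lab] == pytest.approx(100 * val / denom, rel=1e-12)
        assert sum(props.values()) <= 100.0 + 1e-9


class TestProfile:
    def test_identifiable_well_separated_component(self):
        rng = np.random.default_rng(8)
        n = 60
        g = np.repeat(np.arange(12), 5)
        u = rng.normal(0, np.sqrt(0.8), 12)
        v = np.full(n, 0.1)
        y = 0.3 + u[g] + rng.normal(0, np.sqrt(v))
        m = reml_fit(y, np.diag(v), np.ones((n, 1)), [np.arange(n), g])
        grid = np.concatenate([[1e-6], np.geomspace(0.01, 10, 25)])
        prof = profile_component(m, 1, grid)
        assert prof.identifiable
        assert grid[np.argmax(prof.loglik)] == pytest.approx(
            m.sigma2[1], rel=0.5)

    def test_duplicated_grouping_flagged(self):
        rng = np.random.default_rng(9)
        n = 40
        g = np.repeat(np.arange(8), 5)
        v = np.full(n, 0.2)
        y = rng.normal(0.1, np.sqrt(v + 0.5))
        # two identical components: only their sum is identified
        m = reml_fit(y, np.diag(v), np.ones((n, 1)), [g, g.copy()])
        prof = profile_component(m, 0, np.geomspace(1e-4, 5, 20))
        assert not prof.identifiable

    def test_negative_grid_rejected(self, small_effect_set):
        m = fit_model(small_effect_set, ModeratorSpec(["intercept"]),
                      RandomEffectsSpec(), "reptile", multistart=False,
                      with_stats=False)
        with pytest.raises(ValueError):
            profile_component(m, 0, [-1.0, 0.5])


class TestEgger:
    def test_zero_residuals_zero_intercept(self):
        n = 10
        v = np.linspace(0.2, 1.0, n)
        y = np.full(n, 0.4)
        m = reml_fit(y, np.diag(v), np.ones((n, 1)), [np.arange(n)],
                     fixed_sigma2=np.array([0.0]))
        # residuals around the IVW mean are not exactly zero; force them
        m.beta = np.array([0.4])
        res = egger_test(m)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_censoring_small_studies_induces_asymmetry(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 100
        for _ in range(reps):
            v = rng.uniform(0.05, 1.5, 60)
            y = rng.normal(0.0, np.sqrt(v))
            keep = (y > 0) | (v < 0.3)     # censor negative imprecise results
            yk, vk = y[keep], v[keep]
            m = reml_fit(yk, np.diag(vk), np.ones((len(yk), 1)),
                         [np.arange(len(yk))], multistart=False)
            if egger_test(m).p < 0.05:
                hits += 1
        assert hits / reps > 0.5

    def test_too_few_observations(self):
        m = reml_fit(np.array([0.1, 0.2]), np.eye(2), np.ones((2, 1)),
                     [np.arange(2)], fixed_sigma2=np.array([0.0]))
        with pytest.raises(ValueError):
            egger_test(m)


class TestMetaforOracle:
    def test_five_component_fit_matches_rma_mv(self, small_effect_set,
                                               tmp_path):
        """Independent cross-check of the REML engine against metafor."""
        eset = small_effect_set
        spec = ModeratorSpec(["distance", "habitat"])
        m = fit_model(eset, spec, RandomEffectsSpec(), "reptile",
                      with_stats=False)
        X, _ = build_design(eset.table, spec, "reptile")
        tab = eset.table.copy()
        tab["x_dist"], tab["x_hab"] = X[:, 1], X[:, 2]
        tab["obs"] = np.arange(len(tab))
        tab.to_csv(tmp_path / "es.csv", index=False)
        np.savetxt(tmp_path / "V.csv", eset.vcov, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            d <- read.csv('{tmp_path}/es.csv')
            V <- as.matrix(read.csv('{tmp_path}/V.csv', header=FALSE))
            fit <- rma.mv(value, V, mods = ~ x_dist + x_hab,
              random = list(~1|obs, ~1|clade,
                            ~1|interaction(clade, species_id),
                            ~1|source_id,
                            ~1|interaction(source_id, study_id)),
              data=d, method='REML',
              control=list(optimizer='optim', optmethod='BFGS'))
            cat(fit$sigma2, coef(fit), fit$se, sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.strip().splitlines()]
        r_sigma2, r_beta, r_se = vals[:5], vals[5:8], vals[8:11]
        np.testing.assert_allclose(m.sigma2, r_sigma2, atol=2e-3)
        np.testing.assert_allclose(m.beta, r_beta, atol=1e-4)
        np.testing.assert_allclose(m.se, r_se, atol=1e-4)
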