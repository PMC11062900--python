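"""REML engine: covariance construction, likelihood, fitting, tests."""

import numpy as np
import pytest
from scipy import stats

from ermeta import meta


def random_instance(rng, k=None, p=1):
    """A small random meta-analytic instance with grouped years."""
    k = k or int(rng.integers(3, 9))
    v = rng.uniform(0.05, 0.5, k)
    experiment = rng.integers(0, max(2, k // 2), k)
    years = rng.integers(2000, 2012, k)
    X = np.column_stack([np.ones(k)] + [rng.normal(size=k)
                                        for _ in range(p - 1)])
    y = rng.normal(0.3, 0.6, k)
    return y, v, X, experiment, years


def oracle_reml(y, X, V):
    """Independent restricted likelihood via orthonormal error contrasts.

    K spans the orthogonal complement of col(X) with KK' = I; the
    multivariate-normal density of Ky has log-likelihood equal to the
    profiled REML formula plus log|X'X|/2 (Harville's K-invariance term),
    which we subtract to land on the same convention.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    k, p = X.shape
    q, _ = np.linalg.qr(X, mode="complete")
    K = q[:, p:].T
    ll = stats.multivariate_normal(np.zeros(k - p), K @ V @ K.T,
                                   allow_singular=False).logpdf(K @ y)
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    return ll - 0.5 * logdet_xtx


class TestMarginalCovariance:
    def test_fixed_effect_limit_is_diagonal(self, rng):
        v = rng.uniform(0.1, 1.0, 5)
        V = meta.marginal_covariance(v)
        assert np.allclose(V, np.diag(v))

    def test_car_off_diagonal(self):
        V = meta.marginal_covariance(
            [0.1, 0.1], experiment=["A", "A"], years=[3, 5],
            tau2_car=1.0, rho_car=0.5)
        assert V[0, 1] == pytest.approx(0.25)

    def test_cross_experiment_blocks_are_zero(self, rng):
        V = meta.marginal_covariance(
            [0.1, 0.1], experiment=["A", "B"], years=[3, 5],
            sigma2_exp=2.0, tau2_car=1.0, rho_car=0.9)
        assert V[0, 1] == 0.0

    def test_psd(self, rng):
        for _ in range(10):
            y, v, X, experiment, years = random_instance(rng)
            V = meta.marginal_covariance(
                v, experiment, years, sigma2_exp=rng.uniform(0, 1),
                sigma2_dataset=rng.uniform(0, 1),
                tau2_car=rng.uniform(0, 1), rho_car=rng.uniform(0, 0.95))
            assert np.linalg.eigvalsh(V).min() > 0


class TestRemlLoglik:
    def test_closed_form_case(self):
        # k=3, intercept-only, V=I, y=0: -(1/2)[2 ln 2pi + ln 3]
        ll = meta.reml_loglik(np.zeros(3), np.ones((3, 1)), np.eye(3))
        assert ll == pytest.approx(-2.38718, abs=1e-5)

    def test_permutation_invariance(self, rng):
        y, v, X, experiment, years = random_instance(rng, k=7)
        V = meta.marginal_covariance(v, experiment, years, sigma2_exp=0.2,
                                     tau2_car=0.1, rho_car=0.4)
        perm = rng.permutation(7)
        ll1 = meta.reml_loglik(y, X, V)
        ll2 = meta.reml_loglik(y[perm], X[perm], V[np.ix_(perm, perm)])
        assert ll2 == pytest.approx(ll1, abs=1e-10)

    def test_matches_dense_mvn_oracle(self, rng):
        for _ in range(25):
            p = int(rng.integers(1, 3))
            y, v, X, experiment, years = random_instance(rng, p=p)
            V = meta.marginal_covariance(
                v, experiment, years, sigma2_exp=rng.uniform(0, 0.5),
                sigma2_dataset=rng.uniform(0, 0.5),
                tau2_car=rng.uniform(0, 0.5), rho_car=rng.uniform(0, 0.9))
            assert meta.reml_loglik(y, X, V) == pytest.approx(
                oracle_reml(y, X, V), abs=1e-8)

    def test_singular_returns_sentinel(self):
        V = np.zeros((3, 3))
        assert meta.reml_loglik(np.zeros(3), np.ones((3, 1)), V) < -1e200


class TestFit:
    def test_single_effect_limit(self):
        m = meta.fit([0.7], [0.04], use_exp=False, use_dataset=False,
                     use_car=False)
        assert m.beta[0] == pytest.approx(0.7)
        assert m.se[0] == pytest.approx(0.2)

    def test_fixed_effect_closed_form(self):
        y, v = np.array([1.0, 1.0, 4.0]), np.array([1.0, 2.0, 4.0])
        m = meta.fit(y, v, use_exp=False, use_dataset=False, use_car=False)
        assert m.beta[0] == pytest.approx(2.5 / 1.75, rel=1e-12)

    def test_car_degeneracy_rho_zero(self, rng):
        """With rho -> 0 the CAR term is a per-effect variance: pinning
        tau2 into sigma2_dataset must give the same restricted likelihood."""
        y, v, X, experiment, years = random_instance(rng, k=8)
        years = np.arange(8)  # all distinct -> rho^|dy| = 1{i=j} at rho=0
        V1 = meta.marginal_covariance(v, experiment, years, sigma2_exp=0.2,
                                      sigma2_dataset=0.1, tau2_car=0.3,
                                      rho_car=0.0)
        V2 = meta.marginal_covariance(v, experiment, years, sigma2_exp=0.2,
                                      sigma2_dataset=0.4)
        assert meta.reml_loglik(y, X, V1) == pytest.approx(
            meta.reml_loglik(y, X, V2), abs=1e-6)

    def test_relabelling_and_year_shift_invariance(self, rng):
        y, v, X, experiment, years = random_instance(rng, k=10)
        m1 = meta.fit(y, v, experiment=experiment, years=years)
        relabel = np.array([f"exp_{e}" for e in experiment])
        m2 = meta.fit(y, v, experiment=relabel, years=years + 1000)
        assert m2.beta[0] == pytest.approx(m1.beta[0], abs=1e-6)
        assert m2.loglik_reml == pytest.approx(m1.loglik_reml, abs=1e-6)

    def test_aic_requires_ml(self, small_effects):
        df = small_effects
        m = meta.fit(df.estimate, df.variance, experiment=df.experiment_id,
                     years=df.year, ml_refit=True)
        assert np.isfinite(m.aic)
        m2 = meta.fit(df.estimate, df.variance, experiment=df.experiment_id,
                      years=df.year)
        with pytest.raises(ValueError):
            m2.aic


class TestWaldCI:
    def test_normal_quantile_interval(self):
        m = meta.MetaModel(beta=np.array([0.0]), vcov_beta=np.array([[1.0]]),
                           sigma2_exp=0, sigma2_dataset=0, tau2_car=0,
                           rho_car=0, loglik_reml=0.0, k=10, p=1,
                           converged=True, names=["b0"])
        ci = meta.wald_ci(m)
        assert ci["ci_low"][0] == pytest.approx(-1.95996, abs=1e-5)
        assert ci["ci_high"][0] == pytest.approx(1.95996, abs=1e-5)

    def test_degenerate_zero_se(self):
        m = meta.MetaModel(beta=np.array([0.5]), vcov_beta=np.array([[0.0]]),
                           sigma2_exp=0, sigma2_dataset=0, tau2_car=0,
                           rho_car=0, loglik_reml=0.0, k=10, p=1,
                           converged=True, names=["b0"])
        ci = meta.wald_ci(m)
        assert ci["ci_low"][0] == ci["ci_high"][0] == 0.5
        assert ci["p"][0] == 0.0

    def test_level_monotonicity(self):
        m = meta.MetaModel(beta=np.array([1.0]), vcov_beta=np.array([[1.0]]),
                           sigma2_exp=0, sigma2_dataset=0, tau2_car=0,
                           rho_car=0, loglik_reml=0.0, k=10, p=1,
                           converged=True, names=["b0"])
        wide = meta.wald_ci(m, level=0.95)
        narrow = meta.wald_ci(m, level=0.5)
        assert (narrow["ci_high"][0] - narrow["ci_low"][0]) < (
            wide["ci_high"][0] - wide["ci_low"][0])

    def test_refuses_nonconverged(self):
        m = meta.MetaModel(beta=np.array([0.0]), vcov_beta=np.array([[1.0]]),
                           sigma2_exp=0, sigma2_dataset=0, tau2_car=0,
                           rho_car=0, loglik_reml=0.0, k=10, p=1,
                           converged=False, names=["b0"])
        with pytest.raises(ValueError, match="non-converged"):
            meta.wald_ci(m)


class TestQStatistics:
    def _model(self, y, v, X, **kw):
        return meta.fit(y, v, X, use_exp=False, use_dataset=False,
                        use_car=False, **kw)

    def test_zero_q_for_homogeneous(self):
        y = np.full(4, 1.3)
        v = np.full(4, 0.2)
        X = np.ones((4, 1))
        t = meta.q_statistics(y, v, X, self._model(y, v, X))
        assert t.Q_total == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        y, v = np.array([0.0, 2.0]), np.array([1.0, 1.0])
        X = np.ones((2, 1))
        t = meta.q_statistics(y, v, X, self._model(y, v, X))
        assert t.Q_total == pytest.approx(2.0)
        assert t.Q_df == 1
        assert t.Q_p == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_qm_is_wald_chisq_on_moderators(self, rng):
        k = 12
        x = rng.normal(size=k)
        X = np.column_stack([np.ones(k), x])
        y = 0.5 + 0.3 * x + rng.normal(0, 0.3, k)
        v = np.full(k, 0.09)
        m = self._model(y, v, X)
        t = meta.q_statistics(y, v, X, m)
        expected = (m.beta[1] / m.se[1]) ** 2
        assert t.Qm == pytest.approx(expected, rel=1e-9)
        assert t.Qm_df == 1
        assert t.QE_df == k - 2

    def test_saturated_design_has_no_qe(self):
        y, v = np.array([0.0, 2.0]), np.array([1.0, 1.0])
        X = np.eye(2)
        m = self._model(y, v, X)
        t = meta.q_statistics(y, v, X, m)
        assert np.isnan(t.QE)


class TestSerialization:
    def test_json_round_trip(self, small_effects, tmp_path):
        df = small_effects
        m = meta.fit(df.estimate, df.variance, experiment=df.experiment_id,
                     years=df.year)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = meta.MetaModel.from_json(path)
        assert np.allclose(back.beta, m.beta)
        assert np.allclose(back.vcov_beta, m.vcov_beta)
        assert back.rho_car == pytest.approx(m.rho_car)
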