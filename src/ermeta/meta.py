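"""Multilevel random-effects meta-analysis engine.

Fits, by restricted maximum likelihood (REML), the model

    y_i = x_i' beta + u_exp(i) + w_exp(i)(year_i) + u_ds(i) + e_i

where ``u_exp ~ N(0, sigma2_exp)`` is an experiment-level intercept,
``u_ds ~ N(0, sigma2_dataset)`` a dataset-level (per-observation) intercept,
``e_i ~ N(0, v_i)`` the known sampling error, and ``w_exp`` a
continuous-time AR(1) process over measurement years within an experiment
with ``Cov[w(t), w(s)] = tau2_car * rho_car**|t - s|``.  This is the
three-level structure with a CAR term familiar from repeated-measures
meta-analysis; moderators enter through the fixed-effects design matrix.

The marginal covariance is

    V[i,j] = v_i 1{i=j} + sigma2_dataset 1{i=j}
             + (sigma2_exp + tau2_car rho_car**|year_i-year_j|) 1{same exp}

and the restricted log-likelihood is

    -1/2 [ (k-p) ln 2pi + ln|V| + ln|X'V^-1 X| + r'V^-1 r ],

with ``r = y - X beta_hat`` and the GLS ``beta_hat``.  Variance components
are optimized on a log scale (logit scale for rho) with deterministic
multi-start; maximum likelihood refits serve AIC comparison and McFadden's
pseudo-R2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg, optimize, special, stats

__all__ = [
    "MetaModel",
    "HeterogeneityTests",
    "marginal_covariance",
    "reml_loglik",
    "ml_loglik",
    "fit",
    "wald_ci",
    "q_statistics",
]

_NEG_INF = -1e300
_RHO_EPS = 1e-6
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MetaModel:
    """A fitted meta-analytic model."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2_exp: float
    sigma2_dataset: float
    tau2_car: float
    rho_car: float
    loglik_reml: float
    k: int
    p: int
    converged: bool
    method: str = "REML"
    loglik_ml: float | None = None
    names: list = field(default_factory=list)
    boundary: dict = field(default_factory=dict)
    n_theta: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    @property
    def aic(self) -> float:
        """AIC from the maximum-likelihood log-likelihood (fixed + variance
        parameters counted)."""
        if self.loglik_ml is None:
            raise ValueError("fit with ml_refit=True to get an AIC")
        return -2.0 * self.loglik_ml + 2.0 * (self.p + self.n_theta)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["beta"] = np.asarray(self.beta).tolist()
        d["vcov_beta"] = np.asarray(self.vcov_beta).tolist()
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "MetaModel":
        import os

        if isinstance(source, os.PathLike) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            with open(source) as fh:
                d = json.load(fh)
        else:
            d = json.loads(source)
        d["beta"] = np.asarray(d["beta"], dtype=float)
        d["vcov_beta"] = np.asarray(d["vcov_beta"], dtype=float)
        return cls(**d)


def marginal_covariance(
    v, experiment=None, years=None, *,
    sigma2_exp=0.0, sigma2_dataset=0.0, tau2_car=0.0, rho_car=0.0,
) -> np.ndarray:
    """Marginal covariance matrix of the effect sizes.

    ``v`` are the sampling variances; ``experiment`` the grouping labels and
    ``years`` the measurement years (both required whenever the experiment
    intercept or the CAR term is active).
    """
    v = np.asarray(v, dtype=float)
    k = v.size
    V = np.diag(v + sigma2_dataset)
    if sigma2_exp > 0.0 or tau2_car > 0.0:
        if experiment is None:
            raise ValueError("experiment labels required for grouped components")
        codes = np.unique(np.asarray(experiment), return_inverse=True)[1]
        same = codes[:, None] == codes[None, :]
        V += sigma2_exp * same
        if tau2_car > 0.0:
            if years is None:
                raise ValueError("years required for the CAR component")
            years = np.asarray(years, dtype=float)
            dy = np.abs(years[:, None] - years[None, :])
            V += tau2_car * np.power(rho_car, dy) * same
    return V


def _profiled(y, X, V):
    """GLS profile quantities for covariance ``V``.

    ``V`` may be a 1-D array (diagonal covariance fast path) or a full
    matrix.  Returns (logdet_V, XtViX, beta, quad r'V^-1 r) or None when V
    is not positive definite.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if V.ndim == 1:
        if np.any(V <= 0):
            return None
        logdet = float(np.sum(np.log(V)))
        Vi_y = y / V
        Vi_X = X / V[:, None]
    else:
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
        Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ (Vi_y - Vi_X @ beta))
    return logdet, XtViX, logdet_xvx, beta, quad


def reml_loglik(y, X, V) -> float:
    """Restricted log-likelihood for marginal covariance ``V``.

    Returns a large negative sentinel (optimizer-safe) when ``V`` or
    ``X'V^-1 X`` is singular.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    prof = _profiled(y, X, V)
    if prof is None:
        return _NEG_INF
    logdet, _, logdet_xvx, _, quad = prof
    return -0.5 * ((k - p) * _LOG_2PI + logdet + logdet_xvx + quad)


def ml_loglik(y, X, V) -> float:
    """Profile (maximum over beta) log-likelihood for covariance ``V``."""
    k = np.asarray(y).size
    prof = _profiled(y, X, V)
    if prof is None:
        return _NEG_INF
    logdet, _, _, _, quad = prof
    return -0.5 * (k * _LOG_2PI + logdet + quad)


def _dl_tau2(y, v, X):
    """DerSimonian-Laird-style method-of-moments heterogeneity estimate,
    used only to seed the optimizer."""
    w = 1.0 / np.asarray(v, dtype=float)
    prof = _profiled(np.asarray(y, float), X, np.asarray(v, float))
    if prof is None:
        return 0.1
    _, _, _, _, q = prof
    k, p = np.atleast_2d(X).shape
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max((q - (k - p)) / denom, 0.0) if denom > 0 else 0.0


def fit(
    y,
    v,
    X=None,
    *,
    experiment=None,
    years=None,
    use_exp=True,
    use_dataset=True,
    use_car=True,
    method="REML",
    ml_refit=False,
    names=None,
) -> MetaModel:
    """Fit the multilevel meta-analytic model.

    Parameters
    ----------
    y, v
        Effect estimates and their sampling variances (length k).
    X
        Fixed-effects design matrix (k x p); defaults to an intercept.
    experiment, years
        Grouping labels and measurement years; required when ``use_exp`` or
        ``use_car`` is on.
    use_exp, use_dataset, use_car
        Which random components to estimate.  With all three off the model
        collapses to the closed-form inverse-variance weighted (fixed-effect)
        estimator.
    method
        "REML" (default) or "ML".
    ml_refit
        Also refit by ML at convergence to populate ``loglik_ml`` (for AIC
        and pseudo-R2) when ``method`` is "REML".
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if X is None:
        X = np.ones((k, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != k:
        raise ValueError("design matrix row count does not match y")
    p = X.shape[1]
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    if (use_exp or use_car) and experiment is None:
        raise ValueError("experiment labels required")
    if use_car and years is None:
        raise ValueError("years required when the CAR term is enabled")

    active = [nm for nm, flag in
              [("sigma2_exp", use_exp), ("sigma2_dataset", use_dataset),
               ("tau2_car", use_car)] if flag]
    n_var = len(active)
    n_theta = n_var + (1 if use_car else 0)

    diagonal_only = not use_exp and not use_car
    if not diagonal_only:
        codes = np.unique(np.asarray(experiment), return_inverse=True)[1]
        same = codes[:, None] == codes[None, :]
        dy = (np.abs(np.asarray(years, float)[:, None]
                     - np.asarray(years, float)[None, :])
              if use_car else None)

    def build_V(theta):
        s2e = theta.get("sigma2_exp", 0.0)
        s2d = theta.get("sigma2_dataset", 0.0)
        t2 = theta.get("tau2_car", 0.0)
        rho = theta.get("rho_car", 0.0)
        if diagonal_only:
            return v + s2d
        V = (s2e + t2 * np.power(rho, dy)) * same if use_car else s2e * same
        V = V + np.diag(v + s2d)
        return V

    loglik_fn = reml_loglik if method == "REML" else ml_loglik

    def unpack(z):
        z = np.clip(z, -60.0, 60.0)  # keep exp finite during line searches
        theta = {nm: float(np.exp(z[i])) for i, nm in enumerate(active)}
        if use_car:
            theta["rho_car"] = float(special.expit(z[n_var])) * (1.0 - _RHO_EPS)
        return theta

    def negll(z):
        return -loglik_fn(y, X, build_V(unpack(z)))

    if n_theta == 0:
        theta = {}
        converged = True
    else:
        tau2_mom = _dl_tau2(y, v, X)
        base = max(tau2_mom / max(n_var, 1), 1e-4)
        mean_v = float(np.mean(v))
        starts = []
        for scale, rho0 in [(1e-3 * mean_v / base if base else 1e-3, 0.1),
                            (1.0, 0.3), (4.0, 0.7), (0.25, 0.05)]:
            z = np.log(np.full(n_var, max(base * scale, 1e-8)))
            if use_car:
                z = np.append(z, special.logit(rho0))
            starts.append(z)
        best, converged = None, False
        for z0 in starts:
            res = optimize.minimize(
                negll, z0, method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        # polish from the best point with Nelder-Mead (robust near boundaries)
        res = optimize.minimize(
            negll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun <= best.fun:
            best = res
        converged = bool(np.isfinite(best.fun) and best.fun < -_NEG_INF / 2)
        theta = unpack(best.x)

    # boundary diagnostics: variance components estimated ~0 or rho ~1
    boundary = {nm: bool(theta.get(nm, 0.0) < 1e-7) for nm in active}
    if use_car:
        boundary["rho_car"] = bool(theta.get("rho_car", 0.0) > 1.0 - 10 * _RHO_EPS)

    V = build_V(theta)
    prof = _profiled(y, X, V)
    if prof is None:
        raise linalg.LinAlgError("covariance singular at the optimum")
    _, XtViX, _, beta, _ = prof
    vcov = np.linalg.inv(XtViX)
    ll = loglik_fn(y, X, V)

    ll_ml = ml_loglik(y, X, V) if method == "ML" else None
    if ml_refit and method == "REML":
        m_ml = fit(y, v, X, experiment=experiment, years=years,
                   use_exp=use_exp, use_dataset=use_dataset, use_car=use_car,
                   method="ML")
        ll_ml = m_ml.loglik_ml

    return MetaModel(
        beta=beta, vcov_beta=vcov,
        sigma2_exp=theta.get("sigma2_exp", 0.0),
        sigma2_dataset=theta.get("sigma2_dataset", 0.0),
        tau2_car=theta.get("tau2_car", 0.0),
        rho_car=theta.get("rho_car", 0.0),
        loglik_reml=(ll if method == "REML" else np.nan),
        loglik_ml=(ll if method == "ML" else ll_ml),
        k=k, p=p, converged=converged, method=method,
        names=list(names) if names is not None else
        [f"b{i}" for i in range(p)],
        boundary=boundary, n_theta=n_theta,
    )


def wald_ci(model: MetaModel, level: float = 0.95):
    """Per-coefficient Wald summaries: estimate, SE, CI bounds, z, p."""
    import pandas as pd

    if not model.converged:
        raise ValueError("refusing Wald intervals from a non-converged fit")
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    se = model.se
    beta = np.asarray(model.beta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "name": model.names,
        "estimate": beta,
        "se": se,
        "ci_low": beta - z_crit * se,
        "ci_high": beta + z_crit * se,
        "z": z,
        "p": pvals,
    })


@dataclass
class HeterogeneityTests:
    Q_total: float
    Q_df: int
    Q_p: float
    QE: float
    QE_df: int
    QE_p: float
    Qm: float
    Qm_df: int
    Qm_p: float


def _has_intercept(X) -> int | None:
    X = np.atleast_2d(X)
    for j in range(X.shape[1]):
        if np.allclose(X[:, j], 1.0):
            return j
    return None


def q_statistics(y, v, X, model: MetaModel) -> HeterogeneityTests:
    """Q (total), QE (residual) and Qm (omnibus moderator) statistics.

    Q and QE use the fixed-effect inverse-sampling-variance weights
    ``w_i = 1/v_i`` (the conventional Cochran form); Qm is the Wald
    chi-square on the fitted model's non-intercept coefficients.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    w = 1.0 / v

    yw = np.sum(w * y) / np.sum(w)
    Q_total = float(np.sum(w * (y - yw) ** 2))
    Q_df = k - 1
    Q_p = float(stats.chi2.sf(Q_total, Q_df)) if Q_df > 0 else np.nan

    if k > p:
        prof = _profiled(y, X, v)
        if prof is None:
            QE, QE_df, QE_p = np.nan, k - p, np.nan
        else:
            QE = prof[4]
            QE_df = k - p
            QE_p = float(stats.chi2.sf(QE, QE_df))
    else:
        QE, QE_df, QE_p = np.nan, 0, np.nan

    icol = _has_intercept(X)
    idx = [j for j in range(p) if j != icol]
    if idx:
        bm = np.asarray(model.beta, dtype=float)[idx]
        vm = np.asarray(model.vcov_beta, dtype=float)[np.ix_(idx, idx)]
        Qm = float(bm @ np.linalg.solve(vm, bm))
        Qm_df = len(idx)
        Qm_p = float(stats.chi2.sf(Qm, Qm_df))
    else:
        Qm, Qm_df, Qm_p = np.nan, 0, np.nan

    return HeterogeneityTests(Q_total, Q_df, Q_p, float(QE), QE_df, QE_p,
                              Qm, Qm_df, Qm_p)
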