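"""Linear mixed model with one random intercept, fitted by REML, with
Satterthwaite-type degrees of freedom.

The model is y = X beta + Z u + e with u ~ N(0, sigma_u^2 I_g) over g
groups (persons) and e ~ N(0, sigma_e^2 I_n).  The grouped covariance
V_i = sigma_e^2 I + sigma_u^2 J admits closed-form inverses per group, so
the REML criterion is evaluated in O(n) and optimized over the two log
variances.

Degrees of freedom: for a single contrast c the Satterthwaite df is
2 f^2 / (g' A g) with f = c' Cov(beta) c, g its gradient in the variance
parameters and A the asymptotic covariance of the variance parameters
(inverse REML information, obtained numerically).  Joint F tests over a
q-row contrast matrix use the eigen-decomposition construction: per-
eigenvector one-df Satterthwaite values nu_i are pooled through
E = sum nu_i/(nu_i - 2) and ddf = 2E/(E - q), which reduces to the single-
contrast rule at q = 1.

This fitter exists because no installed Python library exposes
Satterthwaite df for mixed models; coefficient estimates are cross-checked
against statsmodels MixedLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import InsufficientDataError

_LOG2PI = np.log(2 * np.pi)


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    stats_ = []
    for gidx in range(codes.max() + 1):
        sel = codes == gidx
        Xi, yi = X[sel], y[sel]
        stats_.append(
            (
                len(yi),
                Xi.T @ Xi,
                Xi.sum(axis=0),  # X_i' 1
                Xi.T @ yi,
                float(yi.sum()),
                float(yi @ yi),
            )
        )
    return stats_


def _assemble(theta: tuple[float, float], gstats, p: int):
    """Return (XtViX, XtViy, ytViy, logdetV) at variance parameters theta."""
    s2u, s2e = theta
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdetV = 0.0
    for n_i, XtX, s, Xty, usum, yty in gstats:
        a = s2u / (s2e + n_i * s2u)
        XtViX += XtX - a * np.outer(s, s)
        XtViy += Xty - a * s * usum
        ytViy += yty - a * usum**2
        logdetV += (n_i - 1) * np.log(s2e) + np.log(s2e + n_i * s2u)
    return XtViX / s2e, XtViy / s2e, ytViy / s2e, logdetV


def _reml_neg2ll(theta, gstats, p, n):
    XtViX, XtViy, ytViy, logdetV = _assemble(theta, gstats, p)
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - beta @ XtViy
    if quad <= 0:
        quad = 1e-12
    return logdetV + logdetXVX + quad + (n - p) * _LOG2PI


@dataclass
class MixedLMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    n: int
    p: int
    n_groups: int
    reml_neg2ll: float
    feature_names: list[str]
    _gstats: object = None

    # -- variance-parameter machinery -------------------------------------
    def _cov_theta(self) -> np.ndarray:
        """Asymptotic covariance of (sigma2_u, sigma2_e): inverse of the
        numerical Hessian of the REML -2 log-likelihood / 2."""
        theta = np.array([self.sigma2_u, self.sigma2_e])
        h = np.maximum(1e-4 * np.abs(theta), 1e-8)

        def f(t):
            return 0.5 * _reml_neg2ll(tuple(np.maximum(t, 1e-12)), self._gstats, self.p, self.n)

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h[i] * h[j])
        try:
            return np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return np.zeros((2, 2))

    def _cov_beta_at(self, theta) -> np.ndarray:
        XtViX, _, _, _ = _assemble(tuple(np.maximum(theta, 1e-12)), self._gstats, self.p)
        return np.linalg.pinv(XtViX)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite df for the contrast c' beta."""
        c = np.asarray(c, dtype=float)
        theta = np.array([self.sigma2_u, self.sigma2_e])
        f0 = float(c @ self.cov_beta @ c)
        h = np.maximum(1e-4 * np.abs(theta), 1e-8)
        grad = np.zeros(2)
        for i in range(2):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
            fp = float(c @ self._cov_beta_at(tp) @ c)
            fm = float(c @ self._cov_beta_at(tm) @ c)
            grad[i] = (fp - fm) / (tp[i] - tm[i])
        denom = float(grad @ self._cov_theta() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)
        df = 2 * f0**2 / denom
        return float(np.clip(df, 1.0, 10 * self.n))

    # -- inference ----------------------------------------------------------
    def t_test(self, c: np.ndarray) -> dict:
        """Contrast estimate, SE, t, Satterthwaite df, two-sided p."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        df = self.satterthwaite_df(c)
        tstat = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tstat), df) if np.isfinite(tstat) else np.nan
        return dict(estimate=est, se=se, t=tstat, df=df, p=float(p))

    def f_test(self, L: np.ndarray) -> dict:
        """Joint F test of L beta = 0 with pooled Satterthwaite ddf."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        M = L @ self.cov_beta @ L.T
        Lb = L @ self.beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        evals, evecs = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            ci = L.T @ evecs[:, i]
            nus.append(self.satterthwaite_df(ci))
        E = sum(nu / (nu - 2) for nu in nus if nu > 2)
        if E > q:
            ddf = 2 * E / (E - q)
        else:
            ddf = float(self.n - self.p)
        p = float(stats.f.sf(F, q, ddf))
        return dict(f=F, df_num=q, df_den=float(ddf), p=p)


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    feature_names: list[str] | None = None,
    fix_sigma2_u: float | None = None,
) -> MixedLMResult:
    """Fit the random-intercept model by REML.

    `fix_sigma2_u=0` constrains the group variance away, collapsing the fit
    to ordinary least squares (an invariant exercised in the tests).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(f"{n} rows cannot identify {p} coefficients")
    codes = np.unique(groups, return_inverse=True)[1]
    gstats = _group_stats(X, y, codes)
    vy = max(float(np.var(y)), 1e-12)

    if fix_sigma2_u is not None:
        s2u = max(float(fix_sigma2_u), 1e-12)

        def neg2ll_e(log_s2e):
            return _reml_neg2ll((s2u, vy * np.exp(log_s2e[0])), gstats, p, n)

        res = optimize.minimize(neg2ll_e, [0.0], method="Nelder-Mead")
        theta = (s2u, vy * float(np.exp(res.x[0])))
    else:

        def neg2ll(lt):
            return _reml_neg2ll((vy * np.exp(lt[0]), vy * np.exp(lt[1])), gstats, p, n)

        best = None
        for start in ([-1.5, -0.3], [-5.0, 0.0], [0.0, -1.0]):
            res = optimize.minimize(
                neg2ll, start, method="Nelder-Mead",
                options=dict(xatol=1e-8, fatol=1e-10, maxiter=2000),
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = (vy * float(np.exp(best.x[0])), vy * float(np.exp(best.x[1])))

    XtViX, XtViy, _, _ = _assemble(theta, gstats, p)
    beta = np.linalg.solve(XtViX, XtViy)
    return MixedLMResult(
        beta=beta,
        cov_beta=np.linalg.pinv(XtViX),
        sigma2_u=theta[0],
        sigma2_e=theta[1],
        n=n,
        p=p,
        n_groups=codes.max() + 1,
        reml_neg2ll=_reml_neg2ll(theta, gstats, p, n),
        feature_names=feature_names or [f"x{i}" for i in range(p)],
        _gstats=gstats,
    )
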