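"""Mixed-effects logistic regression with a single Gaussian random intercept.

Maximum-likelihood estimation of

    y_ij ~ Bernoulli(expit(x_ij' beta + u_j)),   u_j ~ N(0, sigma^2),

marginalising the group intercepts u_j by adaptive Gauss-Hermite quadrature
(Laplace approximation is the one-node special case). This setting — few
grouping levels, many observations per level, as with calendar-year
intercepts in fishery observer data — is where adaptive quadrature is both
accurate and cheap.

The interface follows the statsmodels model/results convention:
``MixedLogit(endog, exog, groups).fit()`` returns a
:class:`MixedLogitResults` with coefficient estimates, Wald standard errors
from the observed information of the marginal likelihood, the maximised
log-likelihood and AIC, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["MixedLogit", "MixedLogitResults", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    pass


def _plain_logit_start(y, X):
    """Cheap fixed-effects start values via a few Newton steps."""
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        p = expit(X @ beta)
        w = np.maximum(p * (1 - p), 1e-10)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-8 * np.eye(X.shape[1]), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


class MixedLogit:
    """Logistic regression with one Gaussian random intercept.

    Parameters
    ----------
    endog : array-like of 0/1
        Binary response.
    exog : array-like (n, p) or DataFrame
        Design matrix including the intercept column.
    groups : array-like
        Grouping labels for the random intercept (e.g. calendar year).
    exog_names : sequence of str, optional
        Column names when ``exog`` is a bare array.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        endog = np.asarray(endog, dtype=float)
        if exog.ndim != 2 or exog.shape[0] != endog.shape[0]:
            raise ValueError("endog and exog shapes do not align")
        if not np.isin(endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.endog = endog
        self.exog = exog
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(exog.shape[1])]
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.n_groups = len(self.group_labels)
        self.nobs = endog.shape[0]
        # Gauss-Hermite nodes/weights for weight function exp(-z^2)
        self._gh_nodes, self._gh_weights = np.polynomial.hermite.hermgauss(15)

    # -- marginal likelihood ------------------------------------------------

    def _group_modes(self, eta, sigma2, u0=None):
        """Per-group posterior modes and curvatures of the random intercept,
        found by a vectorised Newton iteration across groups."""
        g = self.group_idx
        y = self.endog
        u = np.zeros(self.n_groups) if u0 is None else u0.copy()
        for _ in range(50):
            p = expit(eta + u[g])
            grad = np.bincount(g, weights=y - p, minlength=self.n_groups) \
                - u / sigma2
            w = p * (1 - p)
            curv = np.bincount(g, weights=w, minlength=self.n_groups) \
                + 1.0 / sigma2
            step = grad / curv
            step = np.clip(step, -5.0, 5.0)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta + u[g])
        w = p * (1 - p)
        curv = np.bincount(g, weights=w, minlength=self.n_groups) + 1.0 / sigma2
        return u, curv

    def loglike(self, params):
        """Marginal log-likelihood at params = (beta, sigma)."""
        beta, sigma = params[:-1], params[-1]
        y, g = self.endog, self.group_idx
        eta = self.exog @ beta
        if sigma < 1e-8:
            eta_c = np.clip(eta, -35, 35)
            return float(np.sum(y * eta_c - np.log1p(np.exp(eta_c))))
        sigma2 = sigma * sigma
        u_hat, curv = self._group_modes(eta, sigma2,
                                        getattr(self, "_u_warm", None))
        self._u_warm = u_hat  # warm start for the next evaluation
        tau = 1.0 / np.sqrt(curv)                       # (G,)
        # adaptive nodes: u = u_hat + sqrt(2) tau z_k
        z = self._gh_nodes                              # (K,)
        nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
        # log integrand h(u) = sum_i loglik_i(u) + log N(u | 0, sigma^2)
        h = np.empty((self.n_groups, z.size))
        for k in range(z.size):
            eta_k = np.clip(eta + nodes[g, k], -35, 35)
            ll_i = y * eta_k - np.log1p(np.exp(eta_k))
            h[:, k] = np.bincount(g, weights=ll_i, minlength=self.n_groups)
        h += -0.5 * nodes**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        log_w = np.log(self._gh_weights)[None, :] + z[None, :]**2
        log_int = logsumexp(h + log_w, axis=1) \
            + 0.5 * np.log(2.0) + np.log(tau)
        return float(np.sum(log_int))

    def fit(self, start_params=None, maxiter=200,
            sigma_fixed: float | None = None) -> "MixedLogitResults":
        """Maximise the marginal likelihood; sigma is bounded below at 0.

        ``sigma_fixed`` pins the random-intercept SD (0 gives a plain
        fixed-effects logistic fit, used when only one group level exists).
        """
        p = self.exog.shape[1]
        if start_params is None:
            beta0 = _plain_logit_start(self.endog, self.exog)
            start = np.append(beta0, 0.3)
        else:
            start = np.asarray(start_params, dtype=float)
        if sigma_fixed is not None:
            start[-1] = sigma_fixed
            bounds = [(None, None)] * p + [(sigma_fixed, sigma_fixed)]
        else:
            bounds = [(None, None)] * p + [(0.0, 15.0)]
        res = minimize(lambda th: -self.loglike(th), start, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": maxiter,
                                               "ftol": 1e-11, "gtol": 1e-7})
        params = res.x
        converged = bool(res.success)
        boundary = params[-1] < 1e-6
        llf = -res.fun
        cov = np.full((p + 1, p + 1), np.nan)
        try:
            if boundary:
                # variance pinned at zero: report fixed-effect covariance
                # from the plain-logistic observed information
                hess = approx_hess1(params[:p],
                                    lambda b: self.loglike(np.append(b, 0.0)))
                cov[:p, :p] = np.linalg.inv(-hess)
            else:
                hess = approx_hess1(params, lambda th: self.loglike(th))
                cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            converged = False
        if not converged:
            warnings.warn("mixed logit fit did not converge",
                          ConvergenceWarning, stacklevel=2)
        return MixedLogitResults(self, params, cov, llf, converged, boundary)


class MixedLogitResults:
    """Fit results for :class:`MixedLogit`.

    Attributes
    ----------
    params : pandas.Series
        Fixed-effect estimates (named by design column).
    sigma : float
        Random-intercept standard deviation estimate.
    bse : pandas.Series
        Wald standard errors of the fixed effects.
    llf, aic : float
        Maximised marginal log-likelihood; AIC = -2 logL + 2K with
        K = number of fixed effects + 1 variance component.
    """

    def __init__(self, model, params, cov, llf, converged, boundary):
        self.model = model
        p = model.exog.shape[1]
        self.params = pd.Series(params[:p], index=model.exog_names)
        self.sigma = float(params[-1])
        self.cov_params = cov
        self.bse = pd.Series(np.sqrt(np.diag(cov)[:p]),
                             index=model.exog_names)
        self.llf = float(llf)
        self.k_params = p + 1
        self.aic = -2.0 * self.llf + 2.0 * self.k_params \
            if converged else np.inf
        self.converged = converged
        self.variance_at_boundary = bool(boundary)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def predict(self, exog) -> np.ndarray:
        """Probability at random intercept 0 (conditional prediction)."""
        exog = np.asarray(exog, dtype=float)
        return expit(exog @ self.params.to_numpy())

    def summary(self) -> str:
        ci = self.conf_int()
        lines = ["Mixed-effects logistic regression (adaptive GH quadrature)",
                 f"  nobs: {self.model.nobs}   groups: {self.model.n_groups}"
                 f"   logLik: {self.llf:.3f}   AIC: {self.aic:.2f}",
                 f"  random-intercept SD: {self.sigma:.4f}"
                 + ("  [at boundary]" if self.variance_at_boundary else ""),
                 f"  {'term':<22}{'coef':>10}{'se':>10}"
                 f"{'2.5%':>10}{'97.5%':>10}"]
        for name in self.params.index:
            lines.append(
                f"  {name:<22}{self.params[name]:>10.4f}"
                f"{self.bse[name]:>10.4f}{ci.loc[name, 'lower']:>10.4f}"
                f"{ci.loc[name, 'upper']:>10.4f}")
        if not self.converged:
            lines.append("  WARNING: fit did not converge")
        return "\n".join(lines)
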