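"""Logistic random-intercept model fitted by adaptive Gauss-Hermite quadrature.

Model: logit P(y_i = 1) = alpha + beta * treat_i + u_{j(i)}, u_j ~ N(0, tau2).
The per-stratum marginal likelihood integrals are evaluated with adaptive
Gauss-Hermite quadrature (15 nodes by default): each stratum's integrand is
re-centred at its conditional mode and re-scaled by its curvature before
applying the Hermite rule, which keeps the rule accurate even for strata
with many observations.  The three parameters (alpha, beta, log sd) are
maximised with L-BFGS-B; standard errors come from the numerical Hessian
of the marginal log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss  # noqa: F401  (plain rule below)
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_expit

__all__ = ["fit_logistic_random_intercept", "GlmmFit"]

_LOG_SD_MIN = np.log(1e-4)
_LOG_SD_MAX = np.log(20.0)


@dataclass
class GlmmFit:
    alpha: float
    beta: float
    tau2: float
    se_beta: float
    loglik: float
    converged: bool


class _Marginal:
    def __init__(self, y, treat, stratum_index, n_strata, n_nodes=15):
        self.y = np.asarray(y, dtype=float)
        self.treat = np.asarray(treat, dtype=float)
        self.j = np.asarray(stratum_index)
        self.J = n_strata
        self.nodes, self.weights = hermgauss(n_nodes)
        self.signed = 2.0 * self.y - 1.0  # log-lik contribution: log_expit(s * eta)

    def _mode_curvature(self, fixed_eta, sd):
        """Per-stratum mode and curvature of log f_j(v) + log phi(v)."""
        m = np.zeros(self.J)
        for _ in range(50):
            p = expit(fixed_eta + sd * m[self.j])
            score = np.bincount(self.j, weights=(self.y - p), minlength=self.J) * sd - m
            w = p * (1.0 - p)
            curv = np.bincount(self.j, weights=w, minlength=self.J) * sd**2 + 1.0
            step = score / curv
            m += step
            if np.max(np.abs(step)) < 1e-10:
                break
        return m, curv

    def loglik(self, theta):
        alpha, beta, log_sd = theta
        sd = np.exp(log_sd)
        fixed_eta = alpha + beta * self.treat
        m, curv = self._mode_curvature(fixed_eta, sd)
        scale = np.sqrt(2.0 / curv)  # (J,)
        # v_{jk} = m_j + scale_j * x_k
        v = m[:, None] + scale[:, None] * self.nodes[None, :]
        # h_j(v) = sum_i log_expit(s_i (fixed_eta_i + sd v)) - v^2/2 - log sqrt(2 pi)
        total = np.zeros((self.J, len(self.nodes)))
        for k in range(len(self.nodes)):
            contrib = log_expit(self.signed * (fixed_eta + sd * v[self.j, k]))
            total[:, k] = np.bincount(self.j, weights=contrib, minlength=self.J)
        h = total - 0.5 * v**2 - 0.5 * np.log(2.0 * np.pi)
        expo = h + self.nodes[None, :] ** 2
        mx = expo.max(axis=1)
        inner = np.sum(self.weights[None, :] * np.exp(expo - mx[:, None]), axis=1)
        log_integ = np.log(scale) + mx + np.log(inner)
        return float(np.sum(log_integ))


def _numerical_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            ea = np.eye(k)[a] * h
            eb = np.eye(k)[b] * h
            H[a, b] = H[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4 * h * h)
    return H


def fit_logistic_random_intercept(
    y, treat, stratum_index, n_strata, n_nodes: int = 15
) -> GlmmFit:
    """Maximum-likelihood fit of the logistic random-intercept model."""
    y = np.asarray(y, dtype=float)
    treat = np.asarray(treat, dtype=float)
    marg = _Marginal(y, treat, stratum_index, n_strata, n_nodes)

    # moment starting values from the pooled 2x2 table
    p1 = y[treat == 1].mean() if (treat == 1).any() else 0.5
    p0 = y[treat == 0].mean() if (treat == 0).any() else 0.5
    p0c, p1c = np.clip([p0, p1], 0.02, 0.98)
    x0 = np.array(
        [np.log(p0c / (1 - p0c)), np.log(p1c / (1 - p1c)) - np.log(p0c / (1 - p0c)),
         np.log(0.5)]
    )

    res = optimize.minimize(
        lambda th: -marg.loglik(th),
        x0,
        method="L-BFGS-B",
        bounds=[(-30, 30), (-30, 30), (_LOG_SD_MIN, _LOG_SD_MAX)],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    alpha, beta, log_sd = res.x
    tau2 = float(np.exp(2 * log_sd))
    at_zero = log_sd <= _LOG_SD_MIN + 1e-6
    if at_zero:
        tau2 = 0.0

    # observed information; when tau2 hits the boundary, profile only (alpha, beta)
    if at_zero:
        def nll2(ab):
            return -marg.loglik(np.array([ab[0], ab[1], _LOG_SD_MIN]))
        H = _numerical_hessian(nll2, res.x[:2])
        idx = 1
    else:
        H = _numerical_hessian(lambda th: -marg.loglik(th), res.x)
        idx = 1
    try:
        cov = np.linalg.inv(H)
        se_beta = float(np.sqrt(cov[idx, idx]))
    except np.linalg.LinAlgError:
        se_beta = np.nan
    converged = bool(res.success) and np.isfinite(se_beta) and abs(beta) <= 15.0
    return GlmmFit(
        alpha=float(alpha),
        beta=float(beta),
        tau2=tau2,
        se_beta=se_beta,
        loglik=float(-res.fun),
        converged=converged,
    )
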