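"""Correlated binary prognostic factors via a latent-Gaussian threshold model.

Binary covariates with prescribed marginal prevalences and pairwise joint
prevalences are generated by dichotomising a multivariate normal vector at
per-coordinate quantile cut-points.  The pairwise latent correlations are
recovered from the printed (marginal, joint) proportions by inverting the
bivariate-normal orthant probability, so the simulated covariates match the
first two moments of the source dataset exactly (in expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CovariateModel",
    "solve_latent_correlation",
    "build_covariate_model",
    "sample_covariates",
    "stratum_codes",
]

_EPS_RHO = 1e-12


def _orthant_probability(p1: float, p2: float, rho: float) -> float:
    """P(Z1 > z(1-p1), Z2 > z(1-p2)) for standard bivariate normal with corr rho."""
    a = stats.norm.ppf(1.0 - p1)
    b = stats.norm.ppf(1.0 - p2)
    # by symmetry P(Z1 > a, Z2 > b) = P(Z1 < -a, Z2 < -b)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
    return float(mvn.cdf([-a, -b]))


def frechet_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Attainable range of the joint probability P(X1 = X2 = 1)."""
    return max(0.0, p1 + p2 - 1.0), min(p1, p2)


def solve_latent_correlation(
    p1: float, p2: float, p12: float, tol: float = 1e-8
) -> float:
    """Latent correlation reproducing a pairwise joint proportion.

    Finds ``rho`` such that thresholding a standard bivariate normal with
    correlation ``rho`` at the (1-p1), (1-p2) quantiles yields
    ``P(X1 = 1, X2 = 1) = p12``.  Solved by bracketed root-finding on the
    orthant probability; the returned value satisfies ``|P(rho) - p12| < tol``.

    Parameters
    ----------
    p1, p2 : float
        Marginal prevalences in [0, 1].
    p12 : float
        Joint prevalence; must lie within the Fréchet bounds of (p1, p2).

    Returns
    -------
    float
        Correlation in [-1, 1].
    """
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} is not a probability")
    lo, hi = frechet_bounds(p1, p2)
    if not lo - 1e-12 <= p12 <= hi + 1e-12:
        raise ValueError(
            f"joint proportion {p12} outside Fréchet bounds [{lo:.6g}, {hi:.6g}] "
            f"for marginals ({p1}, {p2})"
        )
    # degenerate marginals: joint is determined, correlation is unidentified
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return 0.0
    if abs(p12 - hi) < 1e-12:
        return 1.0
    if abs(p12 - lo) < 1e-12:
        return -1.0

    def f(rho: float) -> float:
        return _orthant_probability(p1, p2, rho) - p12

    rho = optimize.brentq(f, -1.0 + _EPS_RHO, 1.0 - _EPS_RHO, xtol=1e-12, rtol=1e-14)
    if abs(f(rho)) > tol:  # pragma: no cover - brentq converges well inside tol
        raise RuntimeError("latent correlation root-finding did not reach tolerance")
    return float(rho)


def nearest_positive_semidefinite(
    corr: np.ndarray, floor: float = 1e-8, warn_above: float = 0.01
) -> np.ndarray:
    """Repair a symmetric correlation matrix by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it, the matrix is reassembled
    and rescaled to unit diagonal.  A warning is emitted when any eigenvalue
    was moved by more than ``warn_above``.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.size == 0:
        return corr
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= floor:
        return corr
    if floor - w.min() > warn_above:
        warnings.warn(
            f"latent correlation matrix repaired: smallest eigenvalue {w.min():.4g} "
            f"clipped to {floor:g}",
            stacklevel=2,
        )
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass(frozen=True)
class CovariateModel:
    """Joint distribution of binary prognostic factors.

    Attributes
    ----------
    names : tuple of str
        Covariate labels.
    marginal_p : ndarray
        Marginal prevalence per covariate.
    joint_p : dict[(int, int), float]
        Pairwise joint prevalence P(X_c = X_d = 1) keyed by index pair (c < d).
        Pairs not listed are treated as independent.
    latent_corr : ndarray
        Latent-Gaussian correlation matrix (unit diagonal, PSD after repair).
    """

    names: tuple[str, ...]
    marginal_p: np.ndarray
    joint_p: dict[tuple[int, int], float] = field(default_factory=dict)
    latent_corr: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def thresholds(self) -> np.ndarray:
        """Latent cut-points z(1 - p_c); X_c = 1 iff Z_c exceeds its cut-point."""
        return stats.norm.ppf(1.0 - self.marginal_p)


def build_covariate_model(
    marginal_p,
    joint_p: dict[tuple[int, int], float] | None = None,
    names: tuple[str, ...] | None = None,
) -> CovariateModel:
    """Construct a :class:`CovariateModel` from marginal and joint proportions.

    Pairwise latent correlations are solved via
    :func:`solve_latent_correlation`; the assembled matrix is repaired to the
    nearest positive semi-definite correlation matrix if needed.

    Raises
    ------
    ValueError
        If any pair's joint proportion violates its Fréchet bounds (the
        message names the offending pair).
    """
    marginal_p = np.asarray(marginal_p, dtype=float)
    c = marginal_p.size
    if names is None:
        names = tuple(f"x{i}" for i in range(c))
    joint_p = dict(joint_p or {})
    corr = np.eye(c)
    for (i, j), pij in joint_p.items():
        if not (0 <= i < j < c):
            raise ValueError(f"joint_p key {(i, j)} must satisfy 0 <= i < j < C")
        try:
            rho = solve_latent_correlation(marginal_p[i], marginal_p[j], pij)
        except ValueError as exc:
            raise ValueError(f"pair ({names[i]}, {names[j]}): {exc}") from None
        corr[i, j] = corr[j, i] = rho
    corr = nearest_positive_semidefinite(corr)
    return CovariateModel(
        names=tuple(names), marginal_p=marginal_p, joint_p=joint_p, latent_corr=corr
    )


def stratum_codes(X: np.ndarray) -> np.ndarray:
    """Integer stratum code per patient: the binary encoding of the covariate row.

    Two patients share a code iff their covariate rows are identical.  With no
    covariates every patient falls in stratum 0.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (patients x covariates)")
    if X.shape[1] == 0:
        return np.zeros(X.shape[0], dtype=np.int64)
    weights = 2 ** np.arange(X.shape[1], dtype=np.int64)
    return (X.astype(np.int64) @ weights).astype(np.int64)


def sample_covariates(
    model: CovariateModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n covariate rows and their stratum codes.

    Multivariate-normal draws with the model's latent correlation are
    thresholded coordinate-wise at z(1 - p_c).

    Returns
    -------
    X : ndarray of shape (n, C), values 0/1
    stratum : ndarray of shape (n,), binary-encoded covariate combination
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c = model.n_covariates
    if c == 0:
        X = np.zeros((n, 0), dtype=np.int8)
        return X, stratum_codes(X)
    L = np.linalg.cholesky(model.latent_corr + 1e-12 * np.eye(c))
    Z = rng.standard_normal((n, c)) @ L.T
    X = (Z > model.thresholds()).astype(np.int8)
    return X, stratum_codes(X)
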