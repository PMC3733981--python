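"""Treatment-effect estimators for two-arm trials with binary prognostic factors.

Five estimators, uniform interface:

* ``covariate_adjusted`` — regression of outcome on treatment plus each
  covariate as a main effect (linear / logistic / Cox by family);
* ``stratified_fixed`` — regression on treatment plus one indicator per
  observed covariate-combination stratum (for survival the indicators enter
  a Cox model as covariates);
* ``stratified_random`` — a normal random intercept per stratum: linear
  mixed model (REML) for continuous outcomes, logistic random-intercept
  model by adaptive Gauss-Hermite quadrature for binary, Cox model with
  log-normal stratum frailty for survival;
* ``mantel_haenszel`` — pooled odds ratio across strata with the
  Robins-Breslow-Greenland variance (binary only);
* ``stratified_cox`` — Cox partial likelihood with stratum-specific
  baseline hazards (survival only).

All return a :class:`TrialFitResult` holding the treatment effect on the
link scale (mean difference, log odds ratio, or log hazard ratio), its
Wald standard error, a two-sided p-value, and a convergence flag.  A fit
counts as non-converged on optimiser failure, separation-style divergence
(|coefficient| > 15 on the link scale), or a non-finite standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._cox import CoxData, fit_frailty_cox, newton_cox
from ._glmm import fit_logistic_random_intercept
from .frame import TrialFrame

__all__ = [
    "METHODS",
    "AnalysisSpec",
    "TrialFitResult",
    "TrialModel",
    "fit_method",
    "wald_reject",
]

METHODS = (
    "covariate_adjusted",
    "stratified_fixed",
    "stratified_random",
    "mantel_haenszel",
    "stratified_cox",
)
_COEF_CAP = 15.0


@dataclass(frozen=True)
class AnalysisSpec:
    """Estimator choice plus test level."""

    method: str
    family: str
    alpha_level: float = 0.05

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown analysis method {self.method!r}")
        if self.method == "mantel_haenszel" and self.family != "binary":
            raise ValueError("Mantel-Haenszel requires a binary outcome")
        if self.method == "stratified_cox" and self.family != "survival":
            raise ValueError("a stratified Cox model requires a survival outcome")


@dataclass
class TrialFitResult:
    """Treatment-effect estimate with Wald-type inference.

    ``estimate`` is on the link scale: a difference in means (continuous),
    a log odds ratio (binary), or a log hazard ratio (survival).  ``df`` is
    the residual degrees of freedom when a t reference is appropriate
    (linear models), else None and the normal reference applies.  ``tau2``
    is the stratum random-effect variance for random-effects fits.
    """

    method: str
    family: str
    estimate: float
    se: float
    p_value: float
    converged: bool
    df: float | None = None
    tau2: float | None = None
    n: int = 0

    def reject(self, alpha_level: float = 0.05) -> bool:
        return wald_reject(self, alpha_level)

    def conf_int(self, alpha_level: float = 0.05) -> tuple[float, float]:
        q = (
            stats.t.ppf(1 - alpha_level / 2, self.df)
            if self.df is not None
            else stats.norm.ppf(1 - alpha_level / 2)
        )
        return self.estimate - q * self.se, self.estimate + q * self.se

    def summary(self) -> str:
        scale = {
            "continuous": "mean difference",
            "binary": "log odds ratio",
            "survival": "log hazard ratio",
        }[self.family]
        lo, hi = self.conf_int() if self.converged else (np.nan, np.nan)
        lines = [
            "Treatment effect ({}, {})".format(self.method, self.family),
            "=" * 46,
            f"  scale         {scale}",
            f"  n             {self.n}",
            f"  estimate      {self.estimate:.6g}",
            f"  std. error    {self.se:.6g}",
            f"  95% CI        [{lo:.6g}, {hi:.6g}]",
            f"  p-value       {self.p_value:.4g}",
            f"  converged     {self.converged}",
        ]
        if self.tau2 is not None:
            lines.append(f"  stratum var.  {self.tau2:.6g}")
        if self.family in ("binary", "survival") and self.converged:
            ratio = "odds ratio" if self.family == "binary" else "hazard ratio"
            lines.append(f"  {ratio:13s} {np.exp(self.estimate):.6g}")
        return "\n".join(lines)


def wald_reject(result: TrialFitResult, alpha_level: float = 0.05) -> bool:
    """Two-sided Wald test of no treatment effect.

    Linear-model fits are referred to the t distribution with their
    residual degrees of freedom; all other fits use the standard normal.
    """
    if not result.converged:
        raise ValueError("cannot test a non-converged fit; exclude it instead")
    z = abs(result.estimate / result.se)
    if result.df is not None:
        return bool(z > stats.t.ppf(1 - alpha_level / 2, result.df))
    return bool(z > stats.norm.ppf(1 - alpha_level / 2))


def _failed(method, family, n, tau2=None) -> TrialFitResult:
    return TrialFitResult(
        method=method,
        family=family,
        estimate=np.nan,
        se=np.nan,
        p_value=np.nan,
        converged=False,
        tau2=tau2,
        n=n,
    )


def _stratum_dummies(frame: TrialFrame, drop_first: bool = True) -> np.ndarray:
    idx = frame.stratum_index()
    J = idx.max() + 1
    U = np.zeros((frame.n, J))
    U[np.arange(frame.n), idx] = 1.0
    return U[:, 1:] if drop_first else U


def _design(frame: TrialFrame, method: str) -> np.ndarray:
    if method == "covariate_adjusted":
        cols = [frame.arm.astype(float)]
        if frame.X.shape[1]:
            cols.append(frame.X.astype(float))
        return np.column_stack(cols)
    return np.column_stack([frame.arm.astype(float), _stratum_dummies(frame)])


def _drop_uninformative_strata(frame: TrialFrame) -> TrialFrame | None:
    """Profile out strata whose indicator coefficient diverges.

    In a fixed-effects fit, a stratum with no outcome variation (no events
    for survival; all-0 or all-1 outcomes for binary) drives its indicator
    to +/-infinity; the profile-likelihood limit for the remaining
    parameters is exactly the fit with those patients removed, so removal
    is performed up front rather than letting Newton diverge.
    """
    idx = frame.stratum_index()
    if frame.family == "survival":
        has_info = np.bincount(idx, weights=frame.event.astype(float)) > 0
    else:
        mean = np.bincount(idx, weights=frame.y) / np.bincount(idx)
        has_info = (mean > 0) & (mean < 1)
    keep = has_info[idx]
    if not keep.any():
        return None
    if keep.all():
        return frame
    kwargs = (
        {"time": frame.time[keep], "event": frame.event[keep]}
        if frame.family == "survival"
        else {"y": frame.y[keep]}
    )
    return TrialFrame(
        X=frame.X[keep],
        arm=frame.arm[keep],
        family=frame.family,
        stratum=frame.stratum[keep],
        names=frame.names,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# per-family fitters


def _fit_linear(frame: TrialFrame, design: np.ndarray) -> TrialFitResult:
    Xd = sm.add_constant(design, has_constant="add")
    res = sm.OLS(frame.y, Xd).fit()
    est, se = res.params[1], res.bse[1]
    if not np.isfinite(se) or se <= 0:
        return _failed("", frame.family, frame.n)
    return TrialFitResult(
        method="",
        family="continuous",
        estimate=float(est),
        se=float(se),
        p_value=float(res.pvalues[1]),
        converged=True,
        df=float(res.df_resid),
        n=frame.n,
    )


def _fit_logistic(frame: TrialFrame, design: np.ndarray) -> TrialFitResult:
    import warnings

    Xd = sm.add_constant(design, has_constant="add")
    try:
        with warnings.catch_warnings():
            # separation is detected post hoc via the coefficient cap
            warnings.simplefilter("ignore")
            res = sm.GLM(frame.y, Xd, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return _failed("", "binary", frame.n)
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    est, se = params[1], bse[1]
    ok = (
        res.converged
        and np.all(np.isfinite(bse))
        and np.all(np.abs(params) <= _COEF_CAP)
        and se > 0
    )
    if not ok:
        return _failed("", "binary", frame.n)
    z = est / se
    return TrialFitResult(
        method="",
        family="binary",
        estimate=float(est),
        se=float(se),
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        n=frame.n,
    )


def _fit_cox(frame: TrialFrame, design: np.ndarray, strata=None) -> TrialFitResult:
    data = CoxData(frame.time, frame.event, design, strata=strata)
    if data.n_events == 0:
        return _failed("", "survival", frame.n)
    fit = newton_cox(data)
    est = fit.beta[0]
    se = float(np.sqrt(fit.cov[0, 0])) if np.isfinite(fit.cov[0, 0]) else np.nan
    if not fit.converged or not np.isfinite(se) or se <= 0 or abs(est) > _COEF_CAP:
        return _failed("", "survival", frame.n)
    z = est / se
    return TrialFitResult(
        method="",
        family="survival",
        estimate=float(est),
        se=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        n=frame.n,
    )


def _fit_mixedlm(frame: TrialFrame) -> TrialFitResult:
    import warnings

    exog = sm.add_constant(frame.arm.astype(float), has_constant="add")
    groups = frame.stratum_index()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(frame.y, exog, groups=groups).fit(reml=True)
    except Exception:
        return _failed("stratified_random", "continuous", frame.n)
    est, se = res.params[1], res.bse[1]
    tau2 = float(np.asarray(res.cov_re).ravel()[0])
    if not np.isfinite(se) or se <= 0:
        return _failed("stratified_random", "continuous", frame.n, tau2=tau2)
    z = est / se
    return TrialFitResult(
        method="stratified_random",
        family="continuous",
        estimate=float(est),
        se=float(se),
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        tau2=tau2,
        n=frame.n,
    )


def _fit_mantel_haenszel(frame: TrialFrame) -> TrialFitResult:
    idx = frame.stratum_index()
    J = idx.max() + 1
    arm = frame.arm.astype(int)
    y = frame.y.astype(int)
    # per-stratum 2x2: rows = arm (1 then 0), cols = outcome (1 then 0)
    tables = []
    for j in range(J):
        m = idx == j
        a = int(np.sum(m & (arm == 1) & (y == 1)))
        b = int(np.sum(m & (arm == 1) & (y == 0)))
        c = int(np.sum(m & (arm == 0) & (y == 1)))
        d = int(np.sum(m & (arm == 0) & (y == 0)))
        if a + b == 0 or c + d == 0:
            continue  # one arm absent: the stratum carries no information
        tables.append(np.array([[a, b], [c, d]], dtype=float))
    if not tables:
        return _failed("mantel_haenszel", "binary", frame.n)
    st = sm.stats.StratifiedTable(tables)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_or = float(np.log(st.oddsratio_pooled))
        se = float(st.logodds_pooled_se)
    if not (np.isfinite(log_or) and np.isfinite(se) and se > 0):
        return _failed("mantel_haenszel", "binary", frame.n)
    z = log_or / se
    return TrialFitResult(
        method="mantel_haenszel",
        family="binary",
        estimate=log_or,
        se=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        n=frame.n,
    )


def _fit_stratified_random(frame: TrialFrame) -> TrialFitResult:
    if frame.family == "continuous":
        return _fit_mixedlm(frame)
    idx = frame.stratum_index()
    J = int(idx.max()) + 1
    if frame.family == "binary":
        g = fit_logistic_random_intercept(frame.y, frame.arm, idx, J)
        if not g.converged:
            return _failed("stratified_random", "binary", frame.n, tau2=g.tau2)
        z = g.beta / g.se_beta
        return TrialFitResult(
            method="stratified_random",
            family="binary",
            estimate=g.beta,
            se=g.se_beta,
            p_value=float(2 * stats.norm.sf(abs(z))),
            converged=True,
            tau2=g.tau2,
            n=frame.n,
        )
    fit = fit_frailty_cox(frame.time, frame.event, frame.arm, idx, J)
    est = fit.beta[0]
    se = float(np.sqrt(fit.cov[0, 0])) if np.isfinite(fit.cov[0, 0]) else np.nan
    if not fit.converged or not np.isfinite(se) or se <= 0 or abs(est) > _COEF_CAP:
        return _failed("stratified_random", "survival", frame.n, tau2=fit.tau2)
    z = est / se
    return TrialFitResult(
        method="stratified_random",
        family="survival",
        estimate=float(est),
        se=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        tau2=fit.tau2,
        n=frame.n,
    )


def fit_method(frame: TrialFrame, method: str) -> TrialFitResult:
    """Fit one estimator to one realised trial; never raises on data problems."""
    spec = AnalysisSpec(method=method, family=frame.family)
    if np.all(frame.arm == frame.arm[0]):
        return _failed(method, frame.family, frame.n)
    if method == "mantel_haenszel":
        res = _fit_mantel_haenszel(frame)
    elif method == "stratified_cox":
        res = _fit_cox(frame, frame.arm.astype(float)[:, None], strata=frame.stratum)
    elif method == "stratified_random":
        res = _fit_stratified_random(frame)
    else:
        sub = frame
        if method == "stratified_fixed" and frame.family != "continuous":
            sub = _drop_uninformative_strata(frame)
            if sub is None or np.all(sub.arm == sub.arm[0]):
                return _failed(method, frame.family, frame.n)
        design = _design(sub, method)
        if frame.family == "continuous":
            res = _fit_linear(sub, design)
        elif frame.family == "binary":
            res = _fit_logistic(sub, design)
        else:
            res = _fit_cox(sub, design)
        res.n = frame.n
    res.method = spec.method
    return res


class TrialModel:
    """Treatment-effect model for one realised trial.

    Parameters
    ----------
    frame : TrialFrame
        Covariates, arms and outcomes for one trial.
    method : str
        One of :data:`METHODS`.

    Examples
    --------
    >>> model = TrialModel(frame, method="stratified_random")
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, frame: TrialFrame, method: str = "covariate_adjusted"):
        self.frame = frame
        self.spec = AnalysisSpec(method=method, family=frame.family)

    @classmethod
    def from_dataframe(
        cls,
        df,
        method: str,
        family: str,
        covariate_cols: list[str],
    ) -> "TrialModel":
        """Build from a tidy DataFrame with arm, outcome and covariate columns."""
        return cls(
            TrialFrame.from_dataframe(df, family=family, covariate_cols=covariate_cols),
            method=method,
        )

    def fit(self) -> TrialFitResult:
        return fit_method(self.frame, self.spec.method)
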