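"""Outcome generators and intercept / censoring calibration.

Continuous outcomes add Gaussian noise to the linear predictor.  Binary
outcomes use the latent-logistic threshold construction (equivalent to a
Bernoulli draw with logit link).  Survival times come from inverting the
cumulative hazard of a proportional-hazards model with exponential
baseline, followed by administrative censoring.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import expit

from .covariates import CovariateModel, sample_covariates
from .effects import EffectSpec, linear_predictor

__all__ = [
    "gen_continuous",
    "gen_binary",
    "gen_survival",
    "generate_outcome",
    "calibrate_intercept",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be bracketed or reached."""


def gen_continuous(
    eta: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """y = eta + Normal(0, sigma^2) noise."""
    eta = np.asarray(eta, dtype=float)
    return eta + sigma * rng.standard_normal(eta.shape)


def gen_binary(eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent-logistic threshold: y = 1 iff eta + eps > 0, eps ~ Logistic(0, 1).

    Equivalent to y ~ Bernoulli(expit(eta)).
    """
    eta = np.asarray(eta, dtype=float)
    eps = rng.logistic(loc=0.0, scale=1.0, size=eta.shape)
    return (eta + eps > 0).astype(np.int8)


def invert_cumulative_hazard(
    u: np.ndarray, eta: np.ndarray, baseline_rate: float
) -> np.ndarray:
    """Uncensored PH survival time T = -ln(U) * exp(-eta) / lambda.

    This inverts H0(t) = lambda*t at -ln(U)*exp(-eta), the standard
    inverse-cumulative-hazard construction for proportional hazards.
    """
    return -np.log(u) * np.exp(-np.asarray(eta, dtype=float)) / baseline_rate


def gen_survival(
    eta: np.ndarray, effects: EffectSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) under exponential-baseline proportional hazards.

    Raw times are censored administratively at ``effects.censor_time``.
    """
    if effects.baseline_rate is None or effects.censor_time is None:
        raise ValueError("survival generation requires baseline_rate and censor_time")
    eta = np.asarray(eta, dtype=float)
    u = rng.uniform(size=eta.shape)
    t_raw = invert_cumulative_hazard(u, eta, effects.baseline_rate)
    event = (t_raw <= effects.censor_time).astype(np.int8)
    time = np.minimum(t_raw, effects.censor_time)
    return time, event


def generate_outcome(
    effects: EffectSpec,
    X: np.ndarray,
    arm: np.ndarray,
    rng: np.random.Generator,
):
    """Dispatch on family: returns y, or (time, event) for survival."""
    eta = linear_predictor(effects, X, arm)
    if effects.family == "continuous":
        return gen_continuous(eta, effects.sigma, rng)
    if effects.family == "binary":
        return gen_binary(eta, rng)
    return gen_survival(eta, effects, rng)


def calibrate_intercept(
    effects: EffectSpec,
    model: CovariateModel,
    target_control_event_rate: float,
    calibration_n: int = 200_000,
    seed: int = 0,
    tol: float = 2e-3,
) -> EffectSpec:
    """Calibrate the generator to a stated control-arm event rate.

    For binary outcomes, solves for the intercept alpha; for survival
    outcomes, fixes the baseline rate at 1 and solves for the censoring
    cut-point.  A large covariate sample (``calibration_n`` rows) is drawn
    once and the conditional event probability given each sampled covariate
    row is averaged analytically, so the root-finding itself is
    deterministic given the seed:

    * binary:    rate(alpha) = mean expit(alpha + eta_cov)
    * survival:  rate(c)     = mean 1 - exp(-c * exp(eta_cov))

    Both maps are strictly monotone, so bisection brackets cleanly.

    Returns a calibrated copy of ``effects``.
    """
    if not 0.0 < target_control_event_rate < 1.0:
        raise ValueError("target rate must be in (0, 1)")
    if effects.family == "continuous":
        raise ValueError("continuous outcomes have no event rate to calibrate")
    rng = np.random.default_rng(seed)
    X, _ = sample_covariates(model, calibration_n, rng)
    # control arm, intercept stripped: covariate + interaction contribution only
    eta_cov = linear_predictor(effects.with_(alpha=0.0), X, np.zeros(len(X)))

    if effects.family == "binary":

        def rate(alpha: float) -> float:
            return float(np.mean(expit(alpha + eta_cov)))

        lo, hi = -30.0, 30.0
        if not rate(lo) < target_control_event_rate < rate(hi):
            raise CalibrationError("target event rate cannot be bracketed by alpha")
        alpha = optimize.brentq(
            lambda a: rate(a) - target_control_event_rate, lo, hi, xtol=1e-10
        )
        if abs(rate(alpha) - target_control_event_rate) > tol:
            raise CalibrationError("intercept calibration did not reach tolerance")
        return effects.with_(alpha=float(alpha))

    # survival: lambda fixed at 1, solve the administrative censoring cut-point
    exp_eta = np.exp(eta_cov)

    def rate_c(log_c: float) -> float:
        return float(np.mean(-np.expm1(-np.exp(log_c) * exp_eta)))

    lo, hi = -40.0, 40.0
    if not rate_c(lo) < target_control_event_rate < rate_c(hi):
        raise CalibrationError("target event rate cannot be bracketed by censor time")
    log_c = optimize.brentq(
        lambda lc: rate_c(lc) - target_control_event_rate, lo, hi, xtol=1e-12
    )
    if abs(rate_c(log_c) - target_control_event_rate) > tol:
        raise CalibrationError("censoring calibration did not reach tolerance")
    return effects.with_(baseline_rate=1.0, censor_time=float(np.exp(log_c)))
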