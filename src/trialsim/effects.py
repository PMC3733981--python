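"""Outcome-model specifications: linear predictors on the link scale.

An :class:`EffectSpec` holds the data-generating coefficients for one trial
scenario.  For continuous outcomes the coefficients act on the identity
scale; for binary outcomes they are log odds ratios; for time-to-event
outcomes they are log hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .covariates import CovariateModel, build_covariate_model

__all__ = [
    "EffectSpec",
    "linear_predictor",
    "scale_interactions",
    "theoretical_scenario",
    "beta12_grid",
    "prevalence_grid",
]

FAMILIES = ("continuous", "binary", "survival")


@dataclass(frozen=True)
class EffectSpec:
    """Coefficients of the data-generating model on the link scale.

    The linear predictor for patient i is

        eta_i = alpha + beta_treat * arm_i
                + sum_c beta_main[c] * X_ic
                + sum_{c<d} beta_inter[(c, d)] * X_ic * X_id

    Attributes
    ----------
    family : {"continuous", "binary", "survival"}
    alpha : float
        Intercept on the link scale (0 for survival, where the baseline
        hazard plays that role).
    beta_treat : float
        Treatment coefficient: mean difference / log-OR / log-HR.
    beta_main : ndarray
        Main-effect coefficient per covariate.
    beta_inter : dict[(int, int), float]
        Two-way interaction coefficients, keyed by index pair (c < d).
    sigma : float
        Residual SD (continuous family only).
    baseline_rate : float
        Exponential baseline hazard rate lambda (survival only).
    censor_time : float
        Administrative censoring cut-point (survival only).
    """

    family: str
    alpha: float = 0.0
    beta_treat: float = 0.0
    beta_main: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_inter: dict[tuple[int, int], float] = field(default_factory=dict)
    sigma: float | None = None
    baseline_rate: float | None = None
    censor_time: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(
            self, "beta_main", np.asarray(self.beta_main, dtype=float)
        )
        if self.family == "continuous":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("continuous family requires sigma > 0")
        if self.family == "survival":
            if self.baseline_rate is not None and self.baseline_rate <= 0:
                raise ValueError("baseline_rate must be > 0")
            if self.censor_time is not None and self.censor_time < 0:
                raise ValueError("censor_time must be >= 0")

    def with_(self, **kwargs) -> "EffectSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def linear_predictor(
    effects: EffectSpec, X: np.ndarray, arm: np.ndarray | float
) -> np.ndarray:
    """Per-patient linear predictor eta on the link scale."""
    X = np.asarray(X, dtype=float)
    n, c = X.shape
    if effects.beta_main.size != c:
        raise ValueError(
            f"beta_main has {effects.beta_main.size} entries but X has {c} columns"
        )
    eta = effects.alpha + effects.beta_treat * np.asarray(arm, dtype=float)
    eta = np.broadcast_to(eta, (n,)).copy() if np.ndim(eta) == 0 else eta
    if c:
        eta = eta + X @ effects.beta_main
    for (i, j), b in effects.beta_inter.items():
        eta = eta + b * X[:, i] * X[:, j]
    return np.asarray(eta, dtype=float)


def scale_interactions(effects: EffectSpec, factor: float) -> EffectSpec:
    """Multiply every two-way interaction coefficient by ``factor``.

    Scaling acts on the link-scale coefficients, i.e. on log odds / log
    hazard ratios for binary / survival families; main effects, intercept
    and residual scale are untouched.
    """
    return effects.with_(
        beta_inter={k: factor * v for k, v in effects.beta_inter.items()}
    )


def theoretical_scenario(
    beta12: float, p1: float = 0.5, p2: float = 0.5
) -> tuple[CovariateModel, EffectSpec]:
    """Two independent binary balancing factors with an interaction.

    Continuous outcome Y = alpha + beta_treat*arm + 0.5*X1 + 0.5*X2
    + beta12*X1*X2 + eps, eps ~ Normal(0, 1); null treatment effect.
    The covariates are independent, so the joint prevalence is p1*p2.
    """
    model = build_covariate_model(
        [p1, p2], {(0, 1): p1 * p2}, names=("x1", "x2")
    )
    effects = EffectSpec(
        family="continuous",
        alpha=0.0,
        beta_treat=0.0,
        beta_main=np.array([0.5, 0.5]),
        beta_inter={(0, 1): beta12},
        sigma=1.0,
    )
    return model, effects


def beta12_grid() -> np.ndarray:
    """Interaction sweep: beta12 from 0 to 3 in steps of 0.2 (16 points)."""
    return np.round(np.arange(0.0, 3.0 + 1e-9, 0.2), 10)


def prevalence_grid() -> np.ndarray:
    """Prevalence sweep: p1 = p2 from 0.1 to 0.5 in steps of 0.05 (9 points)."""
    return np.round(np.arange(0.10, 0.50 + 1e-9, 0.05), 10)
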