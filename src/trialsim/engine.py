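"""Monte-Carlo engine: replication loop, error/power estimation, calibration.

A :class:`Scenario` couples one data-generating configuration (covariate
model + effect specification) with one or more randomisation schemes and
one or more analysis methods.  Each replication draws covariates once and
one set of outcome noise variates once, then reuses them across every
randomisation scheme and analysis method (common random numbers), so that
method contrasts are estimated with far less Monte-Carlo noise than the
individual rates.

Replication r of a scenario is seeded from
``SeedSequence([master_seed, scenario_tag, r])`` with independent child
streams for covariates, outcome noise and each allocation scheme, so runs
are reproducible and insensitive to the order in which schemes or methods
are listed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import fit_method, wald_reject
from .covariates import CovariateModel, sample_covariates
from .effects import (
    EffectSpec,
    beta12_grid,
    linear_predictor,
    prevalence_grid,
    scale_interactions,
    theoretical_scenario,
)
from .frame import TrialFrame
from .outcomes import CalibrationError, calibrate_intercept, invert_cumulative_hazard
from .randomisation import RandomisationScheme, allocate

__all__ = [
    "Scenario",
    "MCSummary",
    "mc_se",
    "run_scenario",
    "calibrate_power_effect",
    "run_theoretical_grids",
    "run_sensitivity",
]


def _tag(label: str) -> int:
    """Stable 31-bit scenario tag for seeding."""
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration."""

    label: str
    covariate_model: CovariateModel
    effects: EffectSpec
    schemes: tuple[RandomisationScheme, ...]
    methods: tuple[str, ...]
    n_patients: int
    n_reps: int = 5000
    master_seed: int = 0
    mode: str = "type1"
    alpha_level: float = 0.05

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.mode not in ("type1", "power"):
            raise ValueError("mode must be 'type1' or 'power'")

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


@dataclass
class MCSummary:
    """Monte-Carlo summary for one (scheme, method) cell.

    ``rejection_rate`` is the proportion rejecting among converged
    replications (the default denominator); ``rejection_rate_all`` counts
    non-converged replications as non-rejections.  ``mc_se`` is the binomial
    standard error sqrt(r(1-r)/n_converged).
    """

    scenario: str
    method: str
    randomisation: str
    n_attempted: int
    n_converged: int
    rejection_rate: float
    rejection_rate_all: float
    mc_se: float
    mode: str
    unusable: bool = False
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "method": self.method,
            "randomisation": self.randomisation,
            "n_attempted": self.n_attempted,
            "n_converged": self.n_converged,
            "rejection_rate": self.rejection_rate,
            "rejection_rate_all": self.rejection_rate_all,
            "mc_se": self.mc_se,
            "mode": self.mode,
            "unusable": self.unusable,
        }
        d.update(self.extra)
        return d


def mc_se(rate: float, n: int) -> float:
    """Binomial standard error of an estimated proportion."""
    if n <= 0:
        return float("nan")
    return float(np.sqrt(rate * (1.0 - rate) / n))


def _draw_noise(effects: EffectSpec, n: int, rng: np.random.Generator):
    """Allocation-independent outcome noise for one replication."""
    if effects.family == "continuous":
        return effects.sigma * rng.standard_normal(n)
    if effects.family == "binary":
        return rng.logistic(size=n)
    return rng.uniform(size=n)


def _outcome_from_noise(effects: EffectSpec, X, arm, noise):
    """Outcome given covariates, arm and pre-drawn noise (common random numbers)."""
    eta = linear_predictor(effects, X, arm)
    if effects.family == "continuous":
        return {"y": eta + noise}
    if effects.family == "binary":
        return {"y": (eta + noise > 0).astype(np.int8)}
    t_raw = invert_cumulative_hazard(noise, eta, effects.baseline_rate)
    event = (t_raw <= effects.censor_time).astype(np.int8)
    return {"time": np.minimum(t_raw, effects.censor_time), "event": event}


def _scheme_label(s: RandomisationScheme) -> str:
    return s.method


def replication_frames(
    scenario: Scenario, rep: int
) -> dict[str, TrialFrame]:
    """Generate the trial data for one replication, one frame per scheme."""
    tag = _tag(scenario.label)
    root = np.random.SeedSequence([scenario.master_seed, tag, rep])
    cov_ss, noise_ss = root.spawn(2)
    X, stratum = sample_covariates(
        scenario.covariate_model, scenario.n_patients, np.random.default_rng(cov_ss)
    )
    noise = _draw_noise(
        scenario.effects, scenario.n_patients, np.random.default_rng(noise_ss)
    )
    frames = {}
    for scheme in scenario.schemes:
        alloc_ss = np.random.SeedSequence(
            [scenario.master_seed, tag, rep, _tag(scheme.method)]
        )
        arm = allocate(
            scheme,
            np.random.default_rng(alloc_ss),
            n=scenario.n_patients,
            covariates=X,
            stratum_ids=stratum,
        )
        parts = _outcome_from_noise(scenario.effects, X, arm, noise)
        frames[_scheme_label(scheme)] = TrialFrame(
            X=X,
            arm=arm,
            family=scenario.effects.family,
            stratum=stratum,
            names=scenario.covariate_model.names,
            **parts,
        )
    return frames


def run_scenario(
    scenario: Scenario, return_records: bool = False
) -> list[MCSummary] | tuple[list[MCSummary], pd.DataFrame]:
    """Run all replications and summarise every (scheme, method) cell."""
    cells = {
        (s.method, m): {"rej": 0, "conv": 0, "att": 0}
        for s in scenario.schemes
        for m in scenario.methods
    }
    records = []
    for rep in range(scenario.n_reps):
        frames = replication_frames(scenario, rep)
        for scheme in scenario.schemes:
            frame = frames[_scheme_label(scheme)]
            for method in scenario.methods:
                res = fit_method(frame, method)
                cell = cells[(scheme.method, method)]
                cell["att"] += 1
                rejected = False
                if res.converged:
                    cell["conv"] += 1
                    rejected = wald_reject(res, scenario.alpha_level)
                    if rejected:
                        cell["rej"] += 1
                if return_records:
                    records.append(
                        {
                            "scenario": scenario.label,
                            "randomisation": scheme.method,
                            "method": method,
                            "rep": rep,
                            "estimate": res.estimate,
                            "se": res.se,
                            "p_value": res.p_value,
                            "converged": res.converged,
                            "rejected": rejected,
                        }
                    )
    summaries = []
    for (scheme_name, method), cell in cells.items():
        n_conv, n_att = cell["conv"], cell["att"]
        rate = cell["rej"] / n_conv if n_conv else float("nan")
        summaries.append(
            MCSummary(
                scenario=scenario.label,
                method=method,
                randomisation=scheme_name,
                n_attempted=n_att,
                n_converged=n_conv,
                rejection_rate=rate,
                rejection_rate_all=cell["rej"] / n_att if n_att else float("nan"),
                mc_se=mc_se(rate, n_conv),
                mode=scenario.mode,
                unusable=bool(n_conv < 0.5 * n_att),
            )
        )
    if return_records:
        return summaries, pd.DataFrame.from_records(records)
    return summaries


# ---------------------------------------------------------------------------
# power calibration


def _power_once(
    scenario: Scenario, beta_treat: float, n_reps: int, method: str, scheme_name: str
) -> float:
    """Empirical power of one method/scheme cell at a candidate effect size."""
    sub = scenario.with_(
        label=scenario.label + "::powercal",
        effects=scenario.effects.with_(beta_treat=beta_treat),
        schemes=(RandomisationScheme(scheme_name),),
        methods=(method,),
        n_reps=n_reps,
        mode="power",
    )
    (summary,) = run_scenario(sub)
    return summary.rejection_rate


def calibrate_power_effect(
    scenario: Scenario,
    target_power: float = 0.8,
    coarse_reps: int = 500,
    refine_reps: int = 2000,
    band: tuple[float, float] = (0.78, 0.82),
    beta_max: float = 5.0,
) -> float:
    """Treatment effect giving the target power, by stochastic bisection.

    The calibration vehicle is the covariate-adjusted analysis under simple
    randomisation.  Candidate effects reuse identical replication seeds, so
    empirical power is a monotone deterministic function of |beta| and
    bisection brackets cleanly.  The coarse search runs at ``coarse_reps``
    replications; the solution is then refined at ``refine_reps``
    replications with probit-scale secant steps until power lands in
    ``band``.  For binary and survival outcomes the returned effect is
    negative (fewer events on treatment); for continuous it is positive.
    """
    if target_power <= scenario.alpha_level:
        return 0.0
    sign = 1.0 if scenario.effects.family == "continuous" else -1.0

    def power(b_abs: float, reps: int) -> float:
        return _power_once(scenario, sign * b_abs, reps, "covariate_adjusted", "simple")

    lo, p_lo = 0.0, scenario.alpha_level
    hi = 0.25
    p_hi = power(hi, coarse_reps)
    while p_hi < target_power:
        hi *= 2.0
        if hi > beta_max:
            raise CalibrationError(
                f"target power {target_power} unreachable within |beta| <= {beta_max}"
            )
        p_hi = power(hi, coarse_reps)
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        p_mid = power(mid, coarse_reps)
        if p_mid < target_power:
            lo, p_lo = mid, p_mid
        else:
            hi, p_hi = mid, p_mid
        if hi - lo < 1e-3 * max(hi, 1.0):
            break
    beta = 0.5 * (lo + hi)

    z_a = stats.norm.ppf(1 - scenario.alpha_level / 2)
    for _ in range(6):
        p = power(beta, refine_reps)
        if band[0] <= p <= band[1]:
            break
        # secant step on the probit scale: |beta| ~ z_{1-a/2} + z_{power}
        p_c = min(max(p, 0.05), 0.995)
        beta = beta * (z_a + stats.norm.ppf(target_power)) / (z_a + stats.norm.ppf(p_c))
        if beta > beta_max:
            raise CalibrationError("power refinement diverged")
    return float(sign * beta)


# ---------------------------------------------------------------------------
# published scenario grids


def _grid_scenario(
    beta12: float, p: float, master_seed: int, n_reps: int, n_patients: int
) -> Scenario:
    model, effects = theoretical_scenario(beta12, p, p)
    return Scenario(
        label=f"theory_b12={beta12:g}_p={p:g}",
        covariate_model=model,
        effects=effects,
        schemes=(
            RandomisationScheme("stratified_blocks", block_size=2),
            RandomisationScheme("minimisation", assign_prob=0.8),
        ),
        methods=("covariate_adjusted", "stratified_fixed"),
        n_patients=n_patients,
        n_reps=n_reps,
        master_seed=master_seed,
        mode="type1",
    )


def run_theoretical_grids(
    master_seed: int = 0, n_reps: int = 5000, n_patients: int = 250
) -> pd.DataFrame:
    """Both published sweeps of the two-factor interaction scenario.

    Sweep 1: interaction coefficient beta12 in {0, 0.2, ..., 3.0} at
    p1 = p2 = 0.5.  Sweep 2: prevalence p1 = p2 in {0.10, ..., 0.50} at
    beta12 = 1.5.  Four cells each: {stratified blocks, minimisation} x
    {covariate-adjusted, stratified fixed-effects} at n=250 under the null.
    """
    rows = []
    for beta12 in beta12_grid():
        scen = _grid_scenario(float(beta12), 0.5, master_seed, n_reps, n_patients)
        for s in run_scenario(scen):
            rows.append({"sweep": "beta12", "beta12": beta12, "p": 0.5, **s.as_dict()})
    for p in prevalence_grid():
        scen = _grid_scenario(1.5, float(p), master_seed, n_reps, n_patients)
        for s in run_scenario(scen):
            rows.append({"sweep": "prevalence", "beta12": 1.5, "p": p, **s.as_dict()})
    return pd.DataFrame(rows)


def run_sensitivity(
    fixture,
    factors=(1.0, 2.5, 5.0, 7.5, 10.0),
    master_seed: int = 0,
    n_reps: int = 5000,
    n_patients: int = 500,
    calibration_n: int = 200_000,
) -> pd.DataFrame:
    """Interaction-scaling sensitivity analysis for one dataset fixture.

    For each factor the interaction coefficients are multiplied on the link
    scale, the intercept / censoring cut-point is re-calibrated to hold the
    control-arm event rate, and the null scenario (covariate-adjusted
    analysis after stratified permuted blocks, block size 4) is re-run.
    """
    from .datasets import DatasetFixture  # local import to avoid a cycle

    assert isinstance(fixture, DatasetFixture)
    model = fixture.covariate_model()
    rows = []
    for factor in factors:
        effects = scale_interactions(fixture.effect_spec(), float(factor))
        if effects.family != "continuous":
            effects = calibrate_intercept(
                effects,
                model,
                fixture.control_event_rate(n_patients),
                calibration_n=calibration_n,
                seed=_tag(f"{fixture.label}-sens-{factor:g}") % (2**31),
            )
        scen = Scenario(
            label=f"{fixture.label}_sens_x{factor:g}",
            covariate_model=model,
            effects=effects,
            schemes=(RandomisationScheme("stratified_blocks", block_size=4),),
            methods=("covariate_adjusted",),
            n_patients=n_patients,
            n_reps=n_reps,
            master_seed=master_seed,
            mode="type1",
        )
        for s in run_scenario(scen):
            rows.append({"factor": factor, **s.as_dict()})
    return pd.DataFrame(rows)
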