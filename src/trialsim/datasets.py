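"""Registry of the three real-trial-based generator parameterisations.

Each fixture is a small CSV shipped with the package holding, per term,
the prevalence (proportion of patients with the covariate, or with both
covariates of an interaction pair) and the outcome-model parameter: a
linear-regression coefficient for the continuous dataset, an odds ratio
for the binary dataset, a hazard ratio for the survival dataset.  Ratio
parameters enter the generator as their natural logarithms.

The three fixtures:

* ``mist2`` — pleural-infection trial, continuous outcome (change in
  pleural effusion size), residual SD 19.1; 3 covariates, 3 interactions.
* ``augib`` — upper-gastrointestinal-bleeding audit, binary outcome
  (further bleeding), control-arm event rate 23.6% (30.1% for n=100
  scenarios); 4 covariates, 6 interactions.
* ``pbc`` — primary-biliary-cirrhosis trial, time-to-event outcome
  (death), control-arm event rate 40.4%; 4 covariates, 6 interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .covariates import CovariateModel, build_covariate_model
from .effects import EffectSpec

__all__ = ["DatasetFixture", "load_fixture", "FIXTURE_LABELS"]

FIXTURE_LABELS = ("mist2", "augib", "pbc")

_META = {
    "mist2": {
        "family": "continuous",
        "value_type": "coefficient",
        "sigma": 19.1,
        "sample_sizes": (100, 200, 500, 1000),
        "event_rate": None,
        "event_rate_n100": None,
    },
    "augib": {
        "family": "binary",
        "value_type": "odds_ratio",
        "sigma": None,
        "sample_sizes": (100, 200, 500, 1000, 2000),
        "event_rate": 0.236,
        "event_rate_n100": 0.301,
    },
    "pbc": {
        "family": "survival",
        "value_type": "hazard_ratio",
        "sigma": None,
        "sample_sizes": (100, 200, 500, 1000, 2000),
        "event_rate": 0.404,
        "event_rate_n100": 0.404,
    },
}

_EXPECTED_COUNTS = {"mist2": (3, 3), "augib": (4, 6), "pbc": (4, 6)}


@dataclass(frozen=True)
class DatasetFixture:
    """One real-data-based generator parameterisation.

    ``main`` / ``interactions`` are DataFrames with columns
    (name, proportion, value, log_value); proportions are stored as
    decimals (a printed 67% appears as 0.67).
    """

    label: str
    family: str
    value_type: str
    main: pd.DataFrame
    interactions: pd.DataFrame
    sigma: float | None
    sample_sizes: tuple[int, ...]
    _event_rate: float | None
    _event_rate_n100: float | None

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.main["name"])

    def control_event_rate(self, n_patients: int | None = None) -> float:
        """Calibration target for the control-arm event rate.

        The binary dataset uses a higher event rate for its n=100 scenarios
        so enough events occur on the treated arm under the power analysis.
        """
        if self._event_rate is None:
            raise ValueError(f"{self.label} has no event-rate target")
        if n_patients is not None and n_patients <= 100:
            return self._event_rate_n100
        return self._event_rate

    def _pair_index(self) -> dict[tuple[int, int], int]:
        pos = {name: i for i, name in enumerate(self.covariate_names)}
        out = {}
        for row_i, pair in enumerate(self.interactions["name"]):
            a, b = pair.split(":")
            i, j = sorted((pos[a], pos[b]))
            out[(i, j)] = row_i
        return out

    def covariate_model(self) -> CovariateModel:
        joint = {
            key: float(self.interactions["proportion"].iloc[row])
            for key, row in self._pair_index().items()
        }
        return build_covariate_model(
            self.main["proportion"].to_numpy(),
            joint,
            names=self.covariate_names,
        )

    def effect_spec(self, beta_treat: float = 0.0) -> EffectSpec:
        """Data-generating coefficients on the link scale (logs of ratios)."""
        beta_main = self.main["log_value"].to_numpy()
        beta_inter = {
            key: float(self.interactions["log_value"].iloc[row])
            for key, row in self._pair_index().items()
        }
        return EffectSpec(
            family=self.family,
            alpha=0.0,
            beta_treat=beta_treat,
            beta_main=beta_main,
            beta_inter=beta_inter,
            sigma=self.sigma,
            baseline_rate=1.0 if self.family == "survival" else None,
            censor_time=np.inf if self.family == "survival" else None,
        )


def load_fixture(label: str) -> DatasetFixture:
    """Load one of the shipped dataset fixtures by label."""
    if label not in FIXTURE_LABELS:
        raise ValueError(f"unknown fixture {label!r}; choose from {FIXTURE_LABELS}")
    meta = _META[label]
    with resources.files("trialsim.data").joinpath(f"{label}.csv").open() as fh:
        table = pd.read_csv(fh)
    table["log_value"] = (
        table["value"]
        if meta["value_type"] == "coefficient"
        else np.log(table["value"])
    )
    main = table[table["term_type"] == "main"].reset_index(drop=True)
    inter = table[table["term_type"] == "interaction"].reset_index(drop=True)
    n_main, n_inter = _EXPECTED_COUNTS[label]
    if len(main) != n_main or len(inter) != n_inter:
        raise ValueError(f"fixture {label} has unexpected row counts")
    return DatasetFixture(
        label=label,
        family=meta["family"],
        value_type=meta["value_type"],
        main=main,
        interactions=inter,
        sigma=meta["sigma"],
        sample_sizes=meta["sample_sizes"],
        _event_rate=meta["event_rate"],
        _event_rate_n100=meta["event_rate_n100"],
    )
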