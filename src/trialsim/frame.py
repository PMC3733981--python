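"""Per-patient trial dataset container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import stratum_codes

__all__ = ["TrialFrame"]


@dataclass
class TrialFrame:
    """One realised trial: covariates, strata, arms and outcomes.

    Attributes
    ----------
    X : ndarray (n, C) of 0/1
        Binary covariate indicators.
    arm : ndarray (n,) of 0/1
        Treatment assignment.
    y : ndarray (n,) or None
        Outcome value (continuous or binary families).
    time, event : ndarray (n,) or None
        Survival outcome (survival family); event is 1 for observed deaths.
    stratum : ndarray (n,)
        Stratum code, a deterministic function of the covariate row.
    family : str
    names : tuple of str
        Covariate labels (optional; defaults to x0..x{C-1}).
    """

    X: np.ndarray
    arm: np.ndarray
    family: str
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    stratum: np.ndarray | None = None
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.arm = np.asarray(self.arm)
        if self.stratum is None:
            self.stratum = stratum_codes(self.X)
        if self.names is None:
            self.names = tuple(f"x{i}" for i in range(self.X.shape[1]))
        if self.family == "survival":
            if self.time is None or self.event is None:
                raise ValueError("survival frame requires time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=np.int8)
        else:
            if self.y is None:
                raise ValueError(f"{self.family} frame requires y")
            self.y = np.asarray(self.y, dtype=float)

    @property
    def n(self) -> int:
        return len(self.arm)

    def observed_strata(self) -> np.ndarray:
        """Sorted unique stratum codes present in the data."""
        return np.unique(self.stratum)

    def stratum_index(self) -> np.ndarray:
        """Stratum membership re-coded to 0..J-1 over observed strata."""
        return np.searchsorted(self.observed_strata(), self.stratum)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df["stratum"] = self.stratum
        df["arm"] = self.arm
        if self.family == "survival":
            df["time"] = self.time
            df["event"] = self.event
        else:
            df["y"] = self.y
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, family: str, covariate_cols: list[str]
    ) -> "TrialFrame":
        X = df[covariate_cols].to_numpy()
        kwargs = {}
        if family == "survival":
            kwargs = {"time": df["time"].to_numpy(), "event": df["event"].to_numpy()}
        else:
            kwargs = {"y": df["y"].to_numpy()}
        return cls(
            X=X,
            arm=df["arm"].to_numpy(),
            family=family,
            names=tuple(covariate_cols),
            **kwargs,
        )
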