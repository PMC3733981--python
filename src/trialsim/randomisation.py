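"""Sequential treatment allocation for two-arm trials.

Three schemes: simple randomisation (fair coin per patient), stratified
permuted blocks (random blocks balanced within every covariate-combination
stratum), and Pocock–Simpson minimisation with a probabilistic element
(each patient is steered to the arm minimising total marginal imbalance
with a configurable probability, 0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RandomisationScheme",
    "allocate_simple",
    "allocate_stratified_blocks",
    "allocate_minimisation",
    "allocate",
    "assignment_log",
]


@dataclass(frozen=True)
class RandomisationScheme:
    """Configuration for one allocation scheme.

    method : {"simple", "stratified_blocks", "minimisation"}
    block_size : even positive int, stratified blocks only
    assign_prob : probability of assigning the minimisation-preferred arm,
        in (0.5, 1]; 0.8 by default.
    """

    method: str
    block_size: int = 2
    assign_prob: float = 0.8

    def __post_init__(self):
        if self.method not in ("simple", "stratified_blocks", "minimisation"):
            raise ValueError(f"unknown randomisation method {self.method!r}")
        if self.method == "stratified_blocks":
            if self.block_size < 2 or self.block_size % 2 != 0:
                raise ValueError("block_size must be a positive even integer")
        if self.method == "minimisation":
            if not 0.5 < self.assign_prob <= 1.0:
                raise ValueError("assign_prob must lie in (0.5, 1]")


def allocate_simple(n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Independent Bernoulli(0.5) arm per patient."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.integers(0, 2, size=n).astype(np.int8)


def _random_block(half: int, rng: np.random.Generator) -> list[int]:
    block = [0] * half + [1] * half
    rng.shuffle(block)
    return block


def allocate_stratified_blocks(
    stratum_ids: np.ndarray,
    rng: np.random.Generator | int,
    block_size: int = 2,
) -> np.ndarray:
    """Permuted-block allocation within each stratum, in arrival order.

    Each stratum consumes independent random permutations of blocks holding
    ``block_size/2`` patients per arm; a trailing incomplete block is simply
    truncated.  At any point in the sequence the within-stratum imbalance
    |n_A - n_B| cannot exceed block_size/2.
    """
    if block_size < 2 or block_size % 2 != 0:
        raise ValueError("block_size must be a positive even integer")
    stratum_ids = np.asarray(stratum_ids)
    if stratum_ids.size < 1:
        raise ValueError("at least one patient required")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    arms = np.empty(stratum_ids.size, dtype=np.int8)
    pending: dict[int, list[int]] = {}
    for i, s in enumerate(stratum_ids):
        s = int(s)
        queue = pending.get(s)
        if not queue:
            queue = pending[s] = _random_block(block_size // 2, rng)
        arms[i] = queue.pop()
    return arms


def allocate_minimisation(
    covariates: np.ndarray,
    rng: np.random.Generator | int,
    assign_prob: float = 0.8,
) -> np.ndarray:
    """Pocock–Simpson minimisation over binary covariates, in arrival order.

    For each incoming patient and each candidate arm, the imbalance score is
    the sum over the patient's covariates of |n_A - n_B| among previously
    assigned patients sharing that covariate's level, counting the candidate
    assignment itself.  The arm with the smaller score is assigned with
    probability ``assign_prob``; exact ties (including the first patient)
    are broken by a fair coin.  Covariates are weighted equally.
    """
    if not 0.5 < assign_prob <= 1.0:
        raise ValueError("assign_prob must lie in (0.5, 1]")
    X = np.asarray(covariates)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("covariates must be a non-empty 2-d array")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("minimisation covariates must be binary (0/1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, c = X.shape
    X = X.astype(np.intp)
    # counts[k, level, arm] = patients so far with covariate k at that level on that arm
    counts = np.zeros((c, 2, 2), dtype=np.int64)
    arms = np.empty(n, dtype=np.int8)
    cols = np.arange(c)
    # pre-draw the random stream: one tie-break coin and one steering draw each
    coin = rng.integers(0, 2, size=n)
    steer = rng.uniform(size=n)
    for i in range(n):
        levels = X[i]
        cnt = counts[cols, levels]        # (c, 2): per-covariate arm counts at this level
        diff = cnt[:, 0] - cnt[:, 1]
        # candidate arm 0: imbalance |(nA+1) - nB| per covariate; arm 1: |nA - (nB+1)|
        score0 = np.abs(diff + 1).sum()
        score1 = np.abs(diff - 1).sum()
        if score0 == score1:
            arm = coin[i]
        else:
            preferred = 0 if score0 < score1 else 1
            arm = preferred if steer[i] < assign_prob else 1 - preferred
        arms[i] = arm
        counts[cols, levels, arm] += 1
    return arms


def allocate(
    scheme: RandomisationScheme,
    rng: np.random.Generator | int,
    *,
    n: int | None = None,
    covariates: np.ndarray | None = None,
    stratum_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Dispatch to the scheme's allocator."""
    if scheme.method == "simple":
        if n is None:
            n = len(stratum_ids) if stratum_ids is not None else len(covariates)
        return allocate_simple(n, rng)
    if scheme.method == "stratified_blocks":
        if stratum_ids is None:
            raise ValueError("stratified_blocks requires stratum_ids")
        return allocate_stratified_blocks(stratum_ids, rng, scheme.block_size)
    if covariates is None:
        raise ValueError("minimisation requires covariates")
    return allocate_minimisation(covariates, rng, scheme.assign_prob)


def assignment_log(
    stratum_ids: np.ndarray, arms: np.ndarray
) -> pd.DataFrame:
    """Assignment log as a DataFrame: patient_index, stratum_id, arm."""
    return pd.DataFrame(
        {
            "patient_index": np.arange(len(arms)),
            "stratum_id": np.asarray(stratum_ids),
            "arm": np.asarray(arms),
        }
    )
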