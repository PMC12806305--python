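"""Two-sample permutation test on mean percent cholesterol change.

The test statistic is the absolute difference in mean percent cholesterol
change between the diet and control arms,

    t = | mean(d) - mean(c) |,

and the null distribution is built by relabeling the pooled changes into
pseudo-arms of the original sizes. The empirical p-value is the plain
fraction of simulated statistics at least as large as the observed one
(no +1 continuity correction, so p = 0 is attainable and the result is
naturally reported as a bound when it underflows the Monte-Carlo
granularity).

When the label-assignment space C(n, n_diet) is small (<= 10,000 by
default) the null is enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "PermutationResult",
    "observed_statistic",
    "permutation_null",
    "exhaustive_null",
    "permutation_p_value",
    "run_scenario1",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, simulated null, and empirical p-value."""

    t_obs: float
    t_sim: np.ndarray
    n_perm: int
    p_value: float
    method: str  # "monte_carlo" or "exhaustive"


def observed_statistic(diet_changes, control_changes) -> float:
    """Absolute difference in mean percent cholesterol change between arms."""
    d = np.asarray(diet_changes, dtype=float)
    c = np.asarray(control_changes, dtype=float)
    if d.size == 0 or c.size == 0:
        raise InputError("observed_statistic requires both groups non-empty")
    return float(abs(d.mean() - c.mean()))


def exhaustive_null(all_changes, n_diet: int) -> np.ndarray:
    """Statistic under every one of the C(n, n_diet) label assignments."""
    pooled = np.asarray(all_changes, dtype=float)
    n = pooled.size
    n_control = n - n_diet
    if n_diet <= 0 or n_control <= 0:
        raise InputError("both pseudo-group sizes must be positive")
    total = pooled.sum()
    stats = np.empty(comb(n, n_diet))
    for k, idx in enumerate(combinations(range(n), n_diet)):
        s = pooled[list(idx)].sum()
        stats[k] = abs(s / n_diet - (total - s) / n_control)
    return stats


def permutation_null(
    all_changes,
    n_diet: int,
    n_control: int,
    n_perm: int = 2500,
    seed: int | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Simulated null statistics under random relabeling of the pooled values.

    ``method`` is "auto" (exhaustive when the assignment space has at most
    10,000 elements, Monte-Carlo otherwise), "monte_carlo", or
    "exhaustive". Monte-Carlo draws label assignments uniformly with
    replacement; deterministic given ``seed``.
    """
    pooled = np.asarray(all_changes, dtype=float)
    if pooled.size != n_diet + n_control:
        raise InputError(
            f"pooled size {pooled.size} does not match group sizes {n_diet}+{n_control}"
        )
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if method not in ("auto", "monte_carlo", "exhaustive"):
        raise InputError(f"unknown method {method!r}")
    if method == "auto":
        method = "exhaustive" if comb(pooled.size, n_diet) <= EXHAUSTIVE_LIMIT else "monte_carlo"
    if method == "exhaustive":
        return exhaustive_null(pooled, n_diet)

    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    # chunked so the permutation matrix stays modest for large n_perm
    chunk = max(1, min(n_perm, int(4e7) // max(pooled.size, 1)))
    total = pooled.sum()
    for start in range(0, n_perm, chunk):
        rows = min(chunk, n_perm - start)
        order = np.argsort(rng.random((rows, pooled.size)), axis=1)
        s = pooled[order[:, :n_diet]].sum(axis=1)
        stats[start : start + rows] = np.abs(s / n_diet - (total - s) / n_control)
    return stats


def permutation_p_value(t_obs: float, t_sim) -> float:
    """Fraction of simulated statistics at least as large as the observed one."""
    t_sim = np.asarray(t_sim, dtype=float)
    if t_sim.size == 0:
        raise InputError("t_sim must be non-empty")
    return float(np.mean(t_sim >= t_obs))


def run_scenario1(
    cohort: pd.DataFrame,
    n_perm: int = 2500,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Run the full permutation analysis on a two-arm trial cohort.

    ``cohort`` needs columns ``arm`` and ``pct_chol_change`` with both arms
    non-empty.
    """
    diet = cohort.loc[cohort["arm"] == "diet", "pct_chol_change"].to_numpy(dtype=float)
    control = cohort.loc[cohort["arm"] == "control", "pct_chol_change"].to_numpy(dtype=float)
    if diet.size == 0 or control.size == 0:
        raise InputError("cohort must contain both a diet arm and a control arm")
    t_obs = observed_statistic(diet, control)
    pooled = np.concatenate([diet, control])
    used = method
    if used == "auto":
        used = "exhaustive" if comb(pooled.size, diet.size) <= EXHAUSTIVE_LIMIT else "monte_carlo"
    t_sim = permutation_null(pooled, diet.size, control.size, n_perm=n_perm, seed=seed, method=used)
    return PermutationResult(
        t_obs=t_obs,
        t_sim=t_sim,
        n_perm=int(t_sim.size),
        p_value=permutation_p_value(t_obs, t_sim),
        method=used,
    )
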