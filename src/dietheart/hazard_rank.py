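"""Bootstrap rank test on cause-specific CVD death hazards.

Within a trial arm, participants are split into a cholesterol-*decrease*
subgroup (percent change < 0) and a cholesterol-*increase* subgroup
(>= 0). The cause-specific hazard of CVD death in each subgroup is
estimated with the Nelson-Aalen rank estimator of the cumulative hazard,

    H(t) = sum_{event times s <= t} dN(s) / Y(s),

where dN(s) counts CVD deaths at s and Y(s) is the number at risk just
before s (deaths at a time are processed before censorings at that time).
Other-cause deaths and administrative censoring both enter as censored for
the CVD-specific analysis. The estimate is summarized as the time-averaged
hazard H(tau)/tau, a per-year rate, with tau defaulting to the largest
observed time in the arm.

The test statistic is the decrease-minus-increase difference of these
rates. Its null distribution is built by bootstrap: resample the pooled
arm with replacement, assign the first n_dec draws to a pseudo-decrease
subgroup and the rest to pseudo-increase, and recompute the difference.
The two-tailed p-value is the fraction of null differences whose absolute
value reaches the observed absolute difference. A label-permutation null
(no resampling) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "RankTestResult",
    "estimate_hazard",
    "split_subgroups",
    "hazard_difference",
    "bootstrap_null",
    "rank_test_p_value",
    "run_scenario2",
]


@dataclass(frozen=True)
class RankTestResult:
    h_obs: float
    h_sim: np.ndarray
    n_boot: int
    p_value: float
    subgroup_sizes: tuple[int, int]  # (decrease, increase)
    tau: float


def _avg_hazard(times: np.ndarray, deaths: np.ndarray, tau: float) -> float:
    """Time-averaged Nelson-Aalen hazard H(tau)/tau; no input validation."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = deaths[order]
    ut, first = np.unique(t, return_index=True)
    deaths_at = np.add.reduceat(d.astype(np.int64), first)
    at_risk = t.size - first  # everyone with time >= ut is still at risk
    within = ut <= tau
    return float(np.sum(deaths_at[within] / at_risk[within]) / tau)


def estimate_hazard(records: pd.DataFrame, tau: float) -> float:
    """Time-averaged Nelson-Aalen cause-specific hazard, per year.

    ``records`` needs columns ``time`` (> 0, years) and ``is_cvd_death``.
    """
    if len(records) == 0:
        raise InputError("estimate_hazard requires a non-empty record collection")
    if tau <= 0:
        raise InputError(f"tau must be > 0, got {tau!r}")
    times = records["time"].to_numpy(dtype=float)
    deaths = records["is_cvd_death"].to_numpy(dtype=bool)
    return _avg_hazard(times, deaths, tau)


def split_subgroups(arm_cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one arm into (decrease, increase) survival-record collections.

    Decrease means pct_chol_change < 0; a change of exactly 0 counts as
    increase. Other-cause deaths are recoded as censored (cause-specific
    convention), not dropped, so they keep contributing to the risk sets.
    """
    if len(arm_cohort) == 0:
        raise InputError("split_subgroups requires a non-empty arm cohort")
    records = pd.DataFrame(
        {
            "time": arm_cohort["time"].to_numpy(dtype=float),
            "is_cvd_death": (arm_cohort["event"] == "cvd_death").to_numpy(),
        }
    )
    decrease_mask = arm_cohort["pct_chol_change"].to_numpy(dtype=float) < 0
    return (
        records.loc[decrease_mask].reset_index(drop=True),
        records.loc[~decrease_mask].reset_index(drop=True),
    )


def hazard_difference(decrease: pd.DataFrame, increase: pd.DataFrame, tau: float | None = None) -> float:
    """Decrease-minus-increase difference of time-averaged hazards (per year).

    ``tau`` defaults to the maximum observed time across both subgroups.
    """
    if len(decrease) == 0 or len(increase) == 0:
        raise InputError("hazard_difference requires both subgroups non-empty")
    if tau is None:
        tau = float(max(decrease["time"].max(), increase["time"].max()))
    return estimate_hazard(decrease, tau) - estimate_hazard(increase, tau)


def bootstrap_null(
    pooled: pd.DataFrame,
    n_dec: int,
    n_inc: int,
    n_boot: int = 5000,
    tau: float | None = None,
    seed: int | None = None,
    method: str = "bootstrap",
) -> np.ndarray:
    """Null distribution of the hazard difference under no subgroup effect.

    Each iteration draws ``n_dec + n_inc`` records with replacement from
    the pooled arm, assigns the first ``n_dec`` to a pseudo-decrease
    subgroup and the rest to pseudo-increase, and records the difference of
    time-averaged hazards. ``method="permutation"`` shuffles the original
    records into pseudo-subgroups instead of resampling. Deterministic
    given ``seed``.
    """
    if len(pooled) == 0:
        raise InputError("bootstrap_null requires a non-empty pooled collection")
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    if n_dec < 1 or n_inc < 1:
        raise InputError("both pseudo-subgroup sizes must be >= 1")
    if method not in ("bootstrap", "permutation"):
        raise InputError(f"unknown method {method!r}")
    times = pooled["time"].to_numpy(dtype=float)
    deaths = pooled["is_cvd_death"].to_numpy(dtype=bool)
    if tau is None:
        tau = float(times.max())
    rng = np.random.default_rng(seed)
    n_total = n_dec + n_inc
    out = np.empty(n_boot)
    for b in range(n_boot):
        if method == "bootstrap":
            idx = rng.integers(0, times.size, n_total)
        else:
            idx = rng.permutation(times.size)[:n_total]
        t, d = times[idx], deaths[idx]
        out[b] = _avg_hazard(t[:n_dec], d[:n_dec], tau) - _avg_hazard(t[n_dec:], d[n_dec:], tau)
    return out


def rank_test_p_value(h_obs: float, h_sim) -> float:
    """Two-tailed p-value: fraction of |null differences| >= |observed|."""
    h_sim = np.asarray(h_sim, dtype=float)
    if h_sim.size == 0:
        raise InputError("h_sim must be non-empty")
    return float(np.mean(np.abs(h_sim) >= abs(h_obs)))


def run_scenario2(
    cohort: pd.DataFrame,
    arm: str,
    n_boot: int = 5000,
    seed: int | None = None,
    tau: float | None = None,
    method: str = "bootstrap",
) -> RankTestResult:
    """Run the full subgroup hazard comparison for one arm of a trial cohort."""
    arm_cohort = cohort.loc[cohort["arm"] == arm]
    if len(arm_cohort) == 0:
        raise InputError(f"arm {arm!r} is empty or absent from the cohort")
    decrease, increase = split_subgroups(arm_cohort)
    if len(decrease) == 0:
        raise InputError(f"decrease subgroup of arm {arm!r} is empty")
    if len(increase) == 0:
        raise InputError(f"increase subgroup of arm {arm!r} is empty")
    if tau is None:
        tau = float(arm_cohort["time"].max())
    h_obs = hazard_difference(decrease, increase, tau)
    pooled = pd.concat([decrease, increase], ignore_index=True)
    h_sim = bootstrap_null(
        pooled, len(decrease), len(increase), n_boot=n_boot, tau=tau, seed=seed, method=method
    )
    return RankTestResult(
        h_obs=h_obs,
        h_sim=h_sim,
        n_boot=int(h_sim.size),
        p_value=rank_test_p_value(h_obs, h_sim),
        subgroup_sizes=(len(decrease), len(increase)),
        tau=tau,
    )
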