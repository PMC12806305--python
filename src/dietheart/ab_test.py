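"""Binned bootstrap-CI A/B comparison of cholesterol in CVD cases vs. population.

The analysis first screens for confounding between serum total cholesterol
and diastolic blood pressure with the Pearson correlation coefficient

    corr(x, y) = 1/(n-1) * sum_i ((x_i - xbar)/s_x) ((y_i - ybar)/s_y),

with s the n-1 sample standard deviation. If a non-negligible correlation
is present (default threshold |corr| >= 0.1), the cohort is stratified
into diastolic-blood-pressure bins; within each bin the mean cholesterol
of CVD cases (a point) is compared against a percentile-bootstrap
confidence interval for the mean cholesterol of the whole bin population
(cases included). A bin is flagged *associated* when the case mean falls
outside that interval — the tabular equivalent of plotting case-mean dots
against population CI whiskers per pressure stratum.

Note that this dot-versus-population-CI rule is intentionally the simple
visual rule, not a calibrated two-sample test: when cases are a minority
of a bin, the case mean is noisier than the population CI is wide, so the
flag fires on null bins more often than 1 - level (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

__all__ = [
    "BinSpec",
    "BinResult",
    "ABTestResult",
    "pearson_corr",
    "bootstrap_mean_ci",
    "run_scenario3",
]

DEFAULT_EDGES = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0, 120.0)


@dataclass(frozen=True)
class BinSpec:
    """Diastolic-blood-pressure strata with open tails.

    ``edges`` are strictly increasing cut-points; bins are the open lower
    tail (-inf, e0), left-closed right-open intervals [e_i, e_{i+1}) except
    the final finite bin which is closed [e_{k-1}, e_k], and the open upper
    tail (e_k, +inf). Every real value maps to exactly one bin.
    """

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise InputError("BinSpec needs at least two edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise InputError("BinSpec edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def labels(self) -> list[str]:
        e = self.edges
        finite = [f"[{e[i]:g},{e[i + 1]:g})" for i in range(len(e) - 2)]
        finite.append(f"[{e[-2]:g},{e[-1]:g}]")
        return [f"<{e[0]:g}"] + finite + [f">{e[-1]:g}"]

    def assign(self, values) -> np.ndarray:
        """Bin index (0 = lower tail, n_bins-1 = upper tail) per value."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="right")
        # the final finite bin is closed: its right edge belongs to it
        idx[v == self.edges[-1]] = len(self.edges) - 1
        return idx

    def interval(self, index: int) -> tuple[float, float]:
        """(low, high) bounds of a bin, with infinities for the tails."""
        e = self.edges
        if index == 0:
            return (-np.inf, e[0])
        if index == len(e):
            return (e[-1], np.inf)
        return (e[index - 1], e[index])


@dataclass(frozen=True)
class BinResult:
    label: str
    low: float
    high: float
    n_all: int
    n_cvd: int
    mean_all: float
    ci_low: float
    ci_high: float
    mean_cvd: float  # nan when n_cvd == 0
    associated: bool
    insufficient: bool


@dataclass(frozen=True)
class ABTestResult:
    corr: float
    corr_screen_passed: bool
    bins: tuple[BinResult, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.bins])


def pearson_corr(x, y) -> float:
    """Pearson correlation with n-1 sample standard deviations, clamped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InputError("pearson_corr requires at least two observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("pearson_corr is undefined for zero-variance input")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((x.size - 1) * sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def bootstrap_mean_ci(
    values, n_boot: int = 5000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the mean.

    Resamples ``len(values)`` observations with replacement ``n_boot``
    times and returns the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles of the resampled means. Deterministic given ``seed``; for a
    fixed seed the resampled means do not depend on ``level``, so
    intervals at nested levels are themselves nested.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("bootstrap_mean_ci requires non-empty values")
    if not (0 < level < 1):
        raise InputError(f"level must lie in (0, 1), got {level!r}")
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7) // values.size))
    for start in range(0, n_boot, chunk):
        rows = min(chunk, n_boot - start)
        idx = rng.integers(0, values.size, (rows, values.size))
        means[start : start + rows] = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    low, high = np.quantile(means, [alpha, 1 - alpha])
    return float(low), float(high)


def run_scenario3(
    cohort: pd.DataFrame,
    bins: BinSpec | None = None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    corr_threshold: float = 0.1,
    min_bin_n: int = 20,
) -> ABTestResult:
    """Correlation screen plus per-bin case-mean vs. population-CI comparison.

    ``cohort`` needs columns ``total_cholesterol``, ``dbp`` and ``cvd``.
    Bins with fewer than ``min_bin_n`` members or no CVD cases are still
    reported but flagged ``insufficient`` (and never ``associated``).
    """
    if len(cohort) == 0:
        raise InputError("run_scenario3 requires a non-empty cohort")
    bins = bins or BinSpec()
    chol = cohort["total_cholesterol"].to_numpy(dtype=float)
    dbp = cohort["dbp"].to_numpy(dtype=float)
    cvd = cohort["cvd"].to_numpy(dtype=bool)

    corr = pearson_corr(chol, dbp)
    screen = abs(corr) >= corr_threshold

    assignment = bins.assign(dbp)
    labels = bins.labels()
    children = np.random.SeedSequence(seed).spawn(bins.n_bins)
    results = []
    for b in range(bins.n_bins):
        mask = assignment == b
        n_all = int(mask.sum())
        n_cvd = int((mask & cvd).sum())
        low, high = bins.interval(b)
        if n_all == 0:
            results.append(
                BinResult(labels[b], low, high, 0, 0, np.nan, np.nan, np.nan, np.nan, False, True)
            )
            continue
        members = chol[mask]
        mean_all = float(members.mean())
        bin_seed = int(children[b].generate_state(1)[0] & 0x7FFFFFFF)
        ci_low, ci_high = bootstrap_mean_ci(members, n_boot=n_boot, level=level, seed=bin_seed)
        mean_cvd = float(chol[mask & cvd].mean()) if n_cvd else np.nan
        insufficient = n_cvd == 0 or n_all < min_bin_n
        associated = bool(
            not insufficient and (mean_cvd < ci_low or mean_cvd > ci_high)
        )
        results.append(
            BinResult(
                labels[b], low, high, n_all, n_cvd, mean_all, ci_low, ci_high,
                mean_cvd, associated, insufficient,
            )
        )
    return ABTestResult(corr=corr, corr_screen_passed=bool(screen), bins=tuple(results))
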