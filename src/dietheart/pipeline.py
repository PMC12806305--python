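"""Composition of the three analyses into one reproducible, reportable run.

A single master seed fans out deterministically to every stage: stage
seeds are drawn from ``numpy.random.SeedSequence(master_seed)`` in a fixed
order (MCE generation, FHS generation, scenario 1, scenario 2 control,
scenario 2 diet, scenario 3) and kept below 2**31. The run report is a
plain JSON-serializable dict that records every statistic, p-value, seed,
simulated-null sequence, and iteration count needed to recompute the
results from the report alone.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ab_test, cohorts, hazard_rank, permutation
from .errors import ConfigError, InputError

__all__ = ["RunConfig", "run_all", "emit_histogram", "derive_seeds"]

logger = logging.getLogger("dietheart")

STAGES = ("mce_gen", "fhs_gen", "scenario1", "scenario2_control", "scenario2_diet", "scenario3")


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


@dataclass(frozen=True)
class RunConfig:
    """What to run and with which iteration counts, paths, and master seed."""

    scenario: str = "all"  # "1", "2", "3", or "all"
    mce_path: str | None = None
    fhs_path: str | None = None
    generate: bool = True
    mce_config: cohorts.MCEGeneratorConfig | None = None
    fhs_config: cohorts.FHSGeneratorConfig | None = None
    n_perm: int = 2500
    n_boot_hazard: int = 5000
    n_boot_ci: int = 5000
    level: float = 0.95
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in ("1", "2", "3", "all"):
            raise ConfigError(f"scenario must be one of 1/2/3/all, got {self.scenario!r}")
        for fname in ("n_perm", "n_boot_hazard", "n_boot_ci"):
            if int(getattr(self, fname)) < 1:
                raise ConfigError(f"{fname} must be >= 1, got {getattr(self, fname)!r}")
        if not (0 < self.level < 1):
            raise ConfigError(f"level must lie in (0, 1), got {self.level!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")


def _load_mce(config: RunConfig, seed: int) -> pd.DataFrame:
    if config.generate:
        gen = config.mce_config or cohorts.MCEGeneratorConfig()
        gen = cohorts.MCEGeneratorConfig(**{**cohorts.config_to_dict(gen), "seed": seed})
        return cohorts.generate_mce(gen)
    if config.mce_path is None:
        raise InputError("scenario 1/2 requested without an MCE cohort path or --generate")
    return cohorts.read_cohort(config.mce_path, "mce")


def _load_fhs(config: RunConfig, seed: int) -> pd.DataFrame:
    if config.generate:
        gen = config.fhs_config or cohorts.FHSGeneratorConfig()
        gen = cohorts.FHSGeneratorConfig(**{**cohorts.config_to_dict(gen), "seed": seed})
        return cohorts.generate_fhs(gen)
    if config.fhs_path is None:
        raise InputError("scenario 3 requested without an FHS cohort path or --generate")
    return cohorts.read_cohort(config.fhs_path, "fhs")


def run_all(config: RunConfig | None = None) -> dict:
    """Execute the requested scenarios and return the structured report."""
    config = config or RunConfig()
    config.validate()
    seeds = dict(zip(STAGES, derive_seeds(config.seed, len(STAGES))))
    report: dict = {
        "master_seed": int(config.seed),
        "stage_seeds": seeds,
        "alpha": config.alpha,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "timing": {},
    }

    want = config.scenario
    mce = fhs = None
    if want in ("1", "2", "all"):
        t0 = _time.perf_counter()
        mce = _load_mce(config, seeds["mce_gen"])
        report["timing"]["mce_load"] = _time.perf_counter() - t0
        if config.generate:
            gen = config.mce_config or cohorts.MCEGeneratorConfig()
            report["mce_generator_config"] = {
                **cohorts.config_to_dict(gen), "seed": seeds["mce_gen"],
            }
        logger.info("MCE cohort ready: %d rows (%.3fs)", len(mce), report["timing"]["mce_load"])
    if want in ("3", "all"):
        t0 = _time.perf_counter()
        fhs = _load_fhs(config, seeds["fhs_gen"])
        report["timing"]["fhs_load"] = _time.perf_counter() - t0
        if config.generate:
            gen = config.fhs_config or cohorts.FHSGeneratorConfig()
            report["fhs_generator_config"] = {
                **cohorts.config_to_dict(gen), "seed": seeds["fhs_gen"],
            }
        logger.info("FHS cohort ready: %d rows (%.3fs)", len(fhs), report["timing"]["fhs_load"])

    if want in ("1", "all"):
        t0 = _time.perf_counter()
        res = permutation.run_scenario1(mce, n_perm=config.n_perm, seed=seeds["scenario1"])
        report["scenario1"] = {
            "t_obs": res.t_obs,
            "n_perm": res.n_perm,
            "method": res.method,
            "seed": seeds["scenario1"],
            "p_value": res.p_value,
            "reject_null": res.p_value < config.alpha,
            "t_sim": res.t_sim.tolist(),
        }
        report["timing"]["scenario1"] = _time.perf_counter() - t0
        logger.info("scenario 1: t_obs=%.3f p=%.4f (%.3fs)", res.t_obs, res.p_value,
                    report["timing"]["scenario1"])

    if want in ("2", "all"):
        report["scenario2"] = {}
        for arm in ("control", "diet"):
            t0 = _time.perf_counter()
            res = hazard_rank.run_scenario2(
                mce, arm, n_boot=config.n_boot_hazard, seed=seeds[f"scenario2_{arm}"]
            )
            report["scenario2"][arm] = {
                "h_obs": res.h_obs,
                "n_boot": res.n_boot,
                "tau": res.tau,
                "seed": seeds[f"scenario2_{arm}"],
                "subgroup_sizes": {"decrease": res.subgroup_sizes[0], "increase": res.subgroup_sizes[1]},
                "p_value": res.p_value,
                "reject_null": res.p_value < config.alpha,
                "h_sim": res.h_sim.tolist(),
            }
            report["timing"][f"scenario2_{arm}"] = _time.perf_counter() - t0
            logger.info("scenario 2 (%s): h_obs=%.4f p=%.4f (%.3fs)", arm, res.h_obs,
                        res.p_value, report["timing"][f"scenario2_{arm}"])

    if want in ("3", "all"):
        t0 = _time.perf_counter()
        res = ab_test.run_scenario3(
            fhs, n_boot=config.n_boot_ci, level=config.level, seed=seeds["scenario3"]
        )
        report["scenario3"] = {
            "corr": res.corr,
            "corr_screen_passed": res.corr_screen_passed,
            "level": config.level,
            "n_boot": config.n_boot_ci,
            "seed": seeds["scenario3"],
            "bins": [vars(b) for b in res.bins],
        }
        report["timing"]["scenario3"] = _time.perf_counter() - t0
        logger.info("scenario 3: corr=%.3f, %d bins (%.3fs)", res.corr, len(res.bins),
                    report["timing"]["scenario3"])

    return report


def emit_histogram(sim_values, observed: float, path) -> pd.DataFrame:
    """Write a density-normalized histogram of a simulated null plus the observed value.

    Bin widths follow the Freedman-Diaconis rule (a single bin when the
    input is constant). The CSV carries one ``bin`` row per histogram bin
    (left edge, right edge, frequency density) and one final ``observed``
    row, which is the tabular content of a null-histogram-plus-marker
    figure.
    """
    sim = np.asarray(sim_values, dtype=float)
    if sim.size == 0:
        raise InputError("emit_histogram requires non-empty simulated values")
    if np.ptp(sim) == 0:
        edges = np.array([sim[0] - 0.5, sim[0] + 0.5])
        density = np.array([1.0])
    else:
        density, edges = np.histogram(sim, bins="fd", density=True)
    frame = pd.DataFrame(
        {
            "kind": ["bin"] * density.size + ["observed"],
            "left": list(edges[:-1]) + [np.nan],
            "right": list(edges[1:]) + [np.nan],
            "density": list(density) + [np.nan],
            "value": [np.nan] * density.size + [float(observed)],
        }
    )
    frame.to_csv(path, index=False)
    return frame
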