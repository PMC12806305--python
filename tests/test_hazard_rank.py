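"""Nelson-Aalen hazard estimation and the bootstrap rank test."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietheart import (
    InputError,
    MCEGeneratorConfig,
    bootstrap_null,
    estimate_hazard,
    generate_mce,
    hazard_difference,
    rank_test_p_value,
    run_scenario2,
    split_subgroups,
)


def records(times, deaths):
    return pd.DataFrame({"time": times, "is_cvd_death": deaths})


def na_fraction_oracle(times, deaths, tau):
    """Independent exact-rational Nelson-Aalen: H(tau)/tau via Fractions."""
    times = list(times)
    h = Fraction(0)
    for s in sorted({t for t, d in zip(times, deaths) if d and t <= tau}):
        dn = sum(1 for t, d in zip(times, deaths) if d and t == s)
        y = sum(1 for t in times if t >= s)
        h += Fraction(dn, y)
    return h / Fraction(tau)


class TestEstimateHazard:
    def test_hand_computed_three_record_fixture(self):
        # H(3) = 1/3 + 1/1 = 4/3, time-average 4/9
        r = records([1.0, 2.0, 3.0], [True, False, True])
        assert estimate_hazard(r, 3.0) == pytest.approx(4 / 9, rel=1e-12)

    def test_no_deaths_gives_zero(self):
        assert estimate_hazard(records([1.0, 2.0], [False, False]), 2.0) == 0.0

    def test_simultaneous_total_mortality_collapses_to_one_over_tau(self):
        r = records([2.0] * 7, [True] * 7)
        assert estimate_hazard(r, 4.0) == pytest.approx(1 / 4, rel=1e-12)

    @pytest.mark.parametrize(
        "times, deaths, tau",
        [
            ((1, 2, 3), (True, False, True), 3),
            ((1, 1, 2, 4, 4), (True, True, False, True, False), 4),
            ((0.5, 1.5, 1.5, 3.0), (False, True, True, True), 2),
            ((2, 2, 2, 5), (True, False, True, False), 5),
        ],
    )
    def test_matches_exact_rational_oracle_on_tiny_fixtures(self, times, deaths, tau):
        r = records([float(t) for t in times], list(deaths))
        expected = na_fraction_oracle(times, deaths, tau)
        assert estimate_hazard(r, float(tau)) == pytest.approx(float(expected), rel=1e-12)

    def test_matches_lifelines_nelson_aalen(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(15)
        times = rng.exponential(2.0, 200).clip(max=4.5)
        deaths = rng.random(200) < 0.6
        deaths[times == 4.5] = False
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, event_observed=deaths)
        tau = float(times.max())
        expected = float(naf.cumulative_hazard_at_times([tau]).iloc[0]) / tau
        assert estimate_hazard(records(times, deaths), tau) == pytest.approx(expected, rel=1e-9)

    def test_empty_records_and_bad_tau_are_errors(self):
        with pytest.raises(InputError):
            estimate_hazard(records([], []), 1.0)
        with pytest.raises(InputError):
            estimate_hazard(records([1.0], [True]), 0.0)

    @given(
        times=st.lists(st.floats(0.1, 4.0), min_size=2, max_size=8),
        new_time=st.floats(0.1, 4.0),
    )
    def test_adding_a_death_never_decreases_the_estimate(self, times, new_time):
        deaths = [False] * len(times)
        deaths[0] = True
        base = estimate_hazard(records(times, deaths), 5.0)
        # adding one extra CVD death (other records fixed) adds a positive
        # increment at its event time and can only enlarge dN at that time
        more = estimate_hazard(records(times + [new_time], deaths + [True]), 5.0)
        assert more >= base - 1e-12


class TestSplitSubgroups:
    def test_zero_change_belongs_to_the_increase_subgroup(self):
        arm = pd.DataFrame(
            {
                "pct_chol_change": [-1.0, 0.0, 2.0],
                "time": [1.0, 2.0, 3.0],
                "event": ["cvd_death", "censored", "other_death"],
            }
        )
        dec, inc = split_subgroups(arm)
        assert len(dec) == 1 and len(inc) == 2

    def test_other_deaths_are_recoded_as_censored_not_dropped(self):
        arm = pd.DataFrame(
            {
                "pct_chol_change": [-1.0, -2.0, -3.0],
                "time": [1.0, 2.0, 3.0],
                "event": ["other_death", "cvd_death", "censored"],
            }
        )
        dec, _ = split_subgroups(arm)
        # the other-cause death stays in the risk set: 3 records, one event
        assert len(dec) == 3
        assert dec.is_cvd_death.tolist() == [False, True, False]
        # recoding keeps Y(2)=2 (H = 1/2); deleting the row would give H = 1
        assert estimate_hazard(dec, 3.0) == pytest.approx((1 / 2) / 3)

    def test_all_negative_changes_leave_increase_empty_and_test_errors(self):
        cohort = pd.DataFrame(
            {
                "arm": ["diet"] * 3,
                "pct_chol_change": [-1.0, -2.0, -3.0],
                "time": [1.0, 2.0, 3.0],
                "event": ["cvd_death"] * 3,
            }
        )
        with pytest.raises(InputError, match="increase"):
            run_scenario2(cohort, "diet", n_boot=10, seed=0)

    def test_default_diet_arm_splits_into_nonempty_subgroups(self, mce_default):
        dec, inc = split_subgroups(mce_default[mce_default.arm == "diet"])
        assert len(dec) > 0 and len(inc) > 0
        assert len(dec) + len(inc) == 1179


class TestHazardDifference:
    def test_identical_collections_difference_is_zero(self):
        r = records([1.0, 2.0, 3.0], [True, False, True])
        assert hazard_difference(r, r.copy(), 3.0) == 0.0

    def test_empty_subgroup_is_an_error(self):
        r = records([1.0], [True])
        with pytest.raises(InputError):
            hazard_difference(r, records([], []))

    def test_antisymmetric_in_subgroup_roles(self):
        a = records([1.0, 2.0, 4.0], [True, True, False])
        b = records([0.5, 3.0], [False, True])
        assert hazard_difference(a, b, 4.0) == pytest.approx(-hazard_difference(b, a, 4.0))


class TestBootstrapNull:
    def test_pool_without_deaths_gives_identically_zero_null(self):
        pool = records([1.0, 2.0, 3.0, 4.0], [False] * 4)
        sim = bootstrap_null(pool, 2, 2, n_boot=50, seed=1)
        assert (sim == 0).all()

    def test_null_mean_is_near_zero_by_exchangeability(self):
        rng = np.random.default_rng(3)
        pool = records(rng.exponential(2, 300).clip(max=4.5), rng.random(300) < 0.5)
        sim = bootstrap_null(pool, 200, 100, n_boot=2000, tau=4.5, seed=4)
        assert abs(sim.mean()) < 2 * sim.std() / np.sqrt(sim.size)

    def test_fixed_seed_reproduces_the_sequence(self):
        pool = records([1.0, 2.0, 3.0], [True, False, True])
        a = bootstrap_null(pool, 2, 1, n_boot=40, seed=9)
        b = bootstrap_null(pool, 2, 1, n_boot=40, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(InputError):
            bootstrap_null(records([], []), 1, 1, n_boot=5)


class TestRankTestPValue:
    @pytest.mark.parametrize(
        "h_obs, h_sim, expected",
        [
            (0.0, [0.1, -0.2], 1.0),
            (0.1, [-0.2, 0.05, 0.15, -0.01], 0.5),
            (0.5, [-0.2, 0.05, 0.15, -0.01], 0.0),
        ],
    )
    def test_two_tailed_indicator_fraction(self, h_obs, h_sim, expected):
        assert rank_test_p_value(h_obs, h_sim) == expected

    def test_empty_null_is_an_error(self):
        with pytest.raises(InputError):
            rank_test_p_value(0.1, [])


class TestScenario2:
    def test_result_is_self_consistent(self, mce_default):
        res = run_scenario2(mce_default, "control", n_boot=300, seed=6)
        assert res.h_sim.size == res.n_boot == 300
        assert res.p_value == rank_test_p_value(res.h_obs, res.h_sim)
        assert sum(res.subgroup_sizes) == 1176

    def test_swapping_subgroup_roles_negates_h_and_preserves_p(self):
        rng = np.random.default_rng(13)
        a = records(rng.exponential(2, 80).clip(max=4.5), rng.random(80) < 0.5)
        b = records(rng.exponential(3, 80).clip(max=4.5), rng.random(80) < 0.3)
        h_ab = hazard_difference(a, b, 4.5)
        h_ba = hazard_difference(b, a, 4.5)
        assert h_ab == pytest.approx(-h_ba)
        # the bootstrap null never looks at the original labels, only at the
        # pooled records and the two subgroup sizes, so with equal sizes the
        # two-tailed p-value is exactly invariant under the role swap
        pool = pd.concat([a, b], ignore_index=True)
        sim = bootstrap_null(pool, 80, 80, n_boot=500, tau=4.5, seed=2)
        assert rank_test_p_value(h_ab, sim) == rank_test_p_value(h_ba, sim)

    def test_power_pattern_control_rejects_diet_mostly_does_not(self):
        control_rej, diet_rej, n_rep = 0, 0, 25
        for seed in range(200, 200 + n_rep):
            cohort = generate_mce(MCEGeneratorConfig(seed=seed))
            pc = run_scenario2(cohort, "control", n_boot=400, seed=seed + 1).p_value
            pd_ = run_scenario2(cohort, "diet", n_boot=400, seed=seed + 2).p_value
            control_rej += pc < 0.05
            diet_rej += pd_ < 0.05
        assert control_rej / n_rep >= 0.8
        assert diet_rej / n_rep <= 0.5

    def test_absent_arm_is_an_error(self, mce_default):
        with pytest.raises(InputError, match="intervention"):
            run_scenario2(mce_default, "intervention", n_boot=10)
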