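"""Cascade model: steady state, closed-form solution, regime switching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrnapipe import (
    ModelError,
    RateParameters,
    RegimeSchedule,
    Segment,
    simulate_schedule,
    solve_cascade,
    steady_state,
)

from _oracles import rk4_cascade, rk4_schedule
from conftest import random_rate_params


class TestSteadyState:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (dict(sigma=10, k45=2, k35=1, alpha=0.5, kpa3=2), (5.0, 10.0, 2.5)),
            (dict(sigma=0, k45=3, k35=2, alpha=0.7, kpa3=1), (0.0, 0.0, 0.0)),
            (dict(sigma=1, k45=1, k35=1, alpha=1, kpa3=1), (1.0, 1.0, 1.0)),
        ],
    )
    def test_closed_form(self, params, expected):
        np.testing.assert_allclose(
            steady_state(RateParameters(**params)), expected, rtol=1e-14
        )

    def test_zero_rate_has_no_steady_state(self):
        with pytest.raises(ModelError, match="no finite steady state"):
            steady_state(RateParameters(sigma=1, k45=1, k35=1, alpha=0.5, kpa3=0))

    def test_equilibrium_is_fixed_point(self, default_params):
        p = default_params["baseline22"]
        y0 = steady_state(p)
        traj = solve_cascade(p, y0, [1.0, 5.0, 40.0])
        np.testing.assert_allclose(traj, np.tile(y0, (3, 1)), rtol=1e-10)

    def test_monotone_in_k45(self):
        base = dict(sigma=2.0, k35=0.5, alpha=0.6, kpa3=0.4)
        ss_lo = steady_state(RateParameters(k45=0.1, **base))
        ss_hi = steady_state(RateParameters(k45=0.4, **base))
        assert ss_hi[0] < ss_lo[0]  # 45S pool shrinks as processing speeds up
        assert ss_hi[1] == ss_lo[1]  # 35S steady state independent of k45


class TestSolveCascade:
    def test_pulse_decay_example(self):
        # pure decay of an initial 45S pulse through the chain, alpha=1, kpa3=0
        p = RateParameters(sigma=0, k45=1, k35=2, alpha=1, kpa3=0)
        traj = solve_cascade(p, [1, 0, 0], [1.0])[0]
        np.testing.assert_allclose(traj, [0.36788, 0.23254, 0.39958], atol=5e-6)
        oracle = rk4_cascade(p, [1, 0, 0], 1.0, step=1e-4)
        np.testing.assert_allclose(traj, oracle, rtol=1e-6)
        # closed form: e^-t, e^-t - e^-2t, remainder
        np.testing.assert_allclose(traj[0], np.exp(-1.0), rtol=1e-12)
        np.testing.assert_allclose(traj[1], np.exp(-1.0) - np.exp(-2.0), rtol=1e-12)

    def test_zero_state_stays_zero(self):
        p = RateParameters(sigma=0, k45=1.3, k35=0.4, alpha=0.5, kpa3=0.2)
        traj = solve_cascade(p, [0, 0, 0], [0.5, 2.0, 10.0])
        np.testing.assert_allclose(traj, 0.0, atol=1e-15)

    def test_matches_rk4_on_random_draws(self, rng):
        for _ in range(25):
            p = random_rate_params(rng)
            y0 = rng.uniform(0, 5, size=3)
            for t in (0.3, 2.0, 9.0):
                traj = solve_cascade(p, y0, [t])[0]
                oracle = rk4_cascade(p, y0, t, step=1e-3)
                np.testing.assert_allclose(traj, oracle, rtol=1e-6, atol=1e-10)

    @pytest.mark.parametrize(
        "rates",
        [
            dict(k45=0.5, k35=0.5, kpa3=0.2),  # repeated pair
            dict(k45=0.5, k35=0.2, kpa3=0.5),  # repeated outer pair
            dict(k45=0.4, k35=0.4, kpa3=0.4),  # triple
            dict(k45=0.4, k35=0.4 + 1e-9, kpa3=0.4),  # near-degenerate
        ],
    )
    def test_degenerate_rates_match_rk4(self, rates):
        p = RateParameters(sigma=1.2, alpha=0.7, **rates)
        y0 = [3.0, 1.0, 0.5]
        traj = solve_cascade(p, y0, [4.0])[0]
        oracle = rk4_cascade(p, y0, 4.0, step=1e-3)
        np.testing.assert_allclose(traj, oracle, rtol=1e-6)

    def test_conservation_limit(self):
        # sigma=0, alpha=1, kpa3=0: the chain only shuffles mass downstream
        p = RateParameters(sigma=0, k45=0.7, k35=0.31, alpha=1.0, kpa3=0.0)
        y0 = np.array([2.0, 1.0, 0.25])
        traj = solve_cascade(p, y0, np.linspace(0.5, 30, 40))
        np.testing.assert_allclose(traj.sum(axis=1), y0.sum(), atol=1e-9)

    def test_rejects_bad_inputs(self):
        p = RateParameters(sigma=1, k45=1, k35=1, alpha=0.5, kpa3=1)
        with pytest.raises(ModelError, match="invalid model input"):
            solve_cascade(p, [-1, 0, 0], [1.0])
        with pytest.raises(ModelError, match="invalid model input"):
            solve_cascade(p, [1, 0, 0], [2.0, 1.0])
        with pytest.raises(ModelError, match="invalid model input"):
            RateParameters(sigma=1, k45=-0.1, k35=1, alpha=0.5, kpa3=1)
        with pytest.raises(ModelError, match="alpha"):
            RateParameters(sigma=1, k45=0.1, k35=1, alpha=1.5, kpa3=1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        t_end=st.floats(0.1, 50.0),
    )
    def test_non_negativity(self, seed, t_end):
        rng = np.random.default_rng(seed)
        p = random_rate_params(rng)
        y0 = rng.uniform(0, 10, size=3)
        traj = solve_cascade(p, y0, np.linspace(t_end / 10, t_end, 10))
        assert traj.min() >= -1e-12


class TestSchedule:
    def test_validation(self):
        with pytest.raises(ModelError):
            RegimeSchedule([Segment(1.0, 24.0, "heat37")])  # must start at 0
        with pytest.raises(ModelError):
            RegimeSchedule(
                [Segment(0.0, 24.0, "heat37"), Segment(25.0, 48.0, "recovery22")]
            )
        with pytest.raises(ModelError):
            Segment(0.0, 24.0, "tropical")

    def test_single_segment_equals_solve_cascade(self, default_params):
        sched = RegimeSchedule([Segment(0.0, 24.0, "heat37")])
        p = default_params["heat37"]
        y0 = [5.0, 3.5, 2.6]
        times = [2.0, 8.0, 24.0]
        np.testing.assert_allclose(
            simulate_schedule(sched, default_params, y0, times),
            solve_cascade(p, y0, times),
            rtol=1e-12,
        )

    def test_split_segment_with_same_params_is_continuous(self, default_params):
        merged = RegimeSchedule([Segment(0.0, 48.0, "heat37")])
        split = RegimeSchedule(
            [Segment(0.0, 24.0, "heat37"), Segment(24.0, 48.0, "heat37")]
        )
        y0 = [5.0, 3.5, 2.6]
        times = np.linspace(1, 47, 20)
        np.testing.assert_allclose(
            simulate_schedule(split, default_params, y0, times),
            simulate_schedule(merged, default_params, y0, times),
            rtol=1e-10,
        )

    def test_two_regime_trajectory_matches_piecewise_rk4(
        self, default_params, heat_recovery_schedule
    ):
        from rrnapipe import steady_state

        y0 = steady_state(default_params["baseline22"])
        t = 30.0  # 6 h into recovery
        val = simulate_schedule(heat_recovery_schedule, default_params, y0, [t])[0]
        oracle = rk4_schedule(heat_recovery_schedule, default_params, y0, t, step=1e-3)
        np.testing.assert_allclose(val, oracle, rtol=1e-6)

    def test_errors(self, default_params, heat_recovery_schedule):
        y0 = [1.0, 1.0, 1.0]
        with pytest.raises(ModelError, match="time out of schedule range"):
            simulate_schedule(heat_recovery_schedule, default_params, y0, [50.0])
        with pytest.raises(ModelError, match="unparameterized regime"):
            simulate_schedule(
                heat_recovery_schedule, {"heat37": default_params["heat37"]}, y0, [2.0]
            )

    def test_regime_labels_at_boundaries(self, heat_recovery_schedule):
        assert heat_recovery_schedule.regime_at(0.0) == "heat37"
        assert heat_recovery_schedule.regime_at(24.0) == "heat37"
        assert heat_recovery_schedule.regime_at(24.5) == "recovery22"
        with pytest.raises(ModelError):
            heat_recovery_schedule.regime_at(-1.0)
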