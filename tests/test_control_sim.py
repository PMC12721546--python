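"""FOPDT plant, PID primitives, the moving-average filter, and the three loops."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biomag import (
    FOPDTPlant,
    PHPlant,
    PIDGains,
    PIDState,
    StirrerPlant,
    TempControlConfig,
    fopdt_response,
    moving_average,
    pid_step,
    simulate_ph,
    simulate_stirrer,
    simulate_temperature,
)
from biomag.control_sim import (
    ph_from_strong_acid_concentration,
    strong_acid_concentration_from_ph,
)
from biomag.errors import ConfigError

PLANT = FOPDTPlant()  # identified batch-heating plant: K=1.475, tau=990, theta=120


class TestFOPDTResponse:
    def test_step_matches_analytic_solution(self):
        ts = fopdt_response(PLANT, 40.0, t_end=6000.0, dt=1.0)
        final = PLANT.gain * 40.0
        analytic = PLANT.ambient + np.where(
            ts.t > PLANT.dead_time,
            final * (1.0 - np.exp(-(ts.t - PLANT.dead_time) / PLANT.time_constant)),
            0.0,
        )
        assert np.abs(ts.value - analytic).max() <= 1e-3 * final

    def test_dead_time_blocks_early_response(self):
        ts = fopdt_response(PLANT, 40.0, t_end=500.0, dt=1.0)
        assert np.all(ts.value[ts.t <= PLANT.dead_time] == PLANT.ambient)

    def test_one_time_constant_after_delay(self):
        ts = fopdt_response(PLANT, 40.0, t_end=2000.0, dt=1.0)
        idx = int(PLANT.dead_time + PLANT.time_constant)
        rise = (ts.value[idx] - PLANT.ambient) / (PLANT.gain * 40.0)
        assert rise == pytest.approx(1.0 - np.exp(-1.0), abs=2e-3)

    def test_gain_times_step_sets_final_value(self):
        ts = fopdt_response(PLANT, 40.0, t_end=12000.0, dt=2.0)
        assert ts.value[-1] - PLANT.ambient == pytest.approx(59.0, rel=1e-3)

    def test_exact_integrator_independent_of_step(self):
        plant = FOPDTPlant(gain=2.0, time_constant=100.0, dead_time=16.0, ambient=0.0)

        def max_err(dt):
            ts = fopdt_response(plant, 10.0, t_end=600.0, dt=dt)
            analytic = np.where(
                ts.t > plant.dead_time,
                plant.gain * 10.0 * (1.0 - np.exp(-(ts.t - plant.dead_time) / plant.time_constant)),
                0.0,
            )
            return np.abs(ts.value - analytic).max()

        # exact exponential update: only the dead-time rounding matters, and it
        # vanishes when theta is a multiple of dt
        assert max_err(1.0) <= 1e-10
        assert max_err(2.0) <= 1e-10

    def test_coarse_dt_rejected(self):
        with pytest.raises(ConfigError):
            fopdt_response(PLANT, 40.0, t_end=1000.0, dt=200.0)


class TestPIDStep:
    def test_zero_error_zero_state(self):
        u, _ = pid_step(PIDGains(3.3, 0.0033, 82.5), 0.0, PIDState(), 1.0)
        assert u == 0.0

    def test_proportional_only(self):
        u, _ = pid_step(PIDGains(2.0), 1.5, PIDState(), 1.0)
        assert u == pytest.approx(3.0)

    def test_integral_accumulation(self):
        gains = PIDGains(0.0, 0.0033, 0.0)
        state = PIDState()
        for _ in range(100):
            u, state = pid_step(gains, 1.0, state, 1.0)
        assert u == pytest.approx(0.33, rel=1e-9)

    def test_antiwindup_freezes_integral_at_clamp(self):
        gains = PIDGains(0.0, 1.0, 0.0)
        state = PIDState()
        for _ in range(50):
            u, state = pid_step(gains, 1.0, state, 1.0, u_min=0.0, u_max=2.0)
        assert u == 2.0
        assert state.integral <= 3.0  # stopped growing once saturated


class TestMovingAverage:
    def test_partial_history_head(self):
        assert moving_average([1.0, 2.0, 3.0, 4.0], 2).tolist() == [1.0, 1.5, 2.5, 3.5]

    def test_window_one_is_identity(self):
        x = [3.0, -1.0, 2.5]
        assert moving_average(x, 1).tolist() == x

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=50),
        window=st.integers(1, 10),
    )
    def test_constant_preserved_and_length_kept(self, values, window):
        out = moving_average(values, window)
        assert len(out) == len(values)
        const = moving_average([7.5] * len(values), window)
        assert np.allclose(const, 7.5)

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigError):
            moving_average([1.0], 0)


class TestTemperatureLoop:
    def test_settles_within_one_degree(self):
        res = simulate_temperature(PLANT, TempControlConfig(setpoint=35.0), t_end=7200.0, dt=1.0)
        assert abs(res.steady_state_error) < 1.0
        assert res.stabilization_time is not None

    def test_setpoint_at_ambient_keeps_heater_off(self):
        res = simulate_temperature(PLANT, TempControlConfig(setpoint=PLANT.ambient),
                                   t_end=2000.0, dt=1.0)
        assert np.all(res.series.actuator == 0.0)
        assert "full-power" not in set(res.series.mode)

    def test_mode_transition_at_twenty_percent_rise(self):
        cfg = TempControlConfig(setpoint=35.0)
        res = simulate_temperature(PLANT, cfg, t_end=3000.0, dt=1.0)
        modes = res.series.mode
        first_pid = int(np.nonzero(modes != "full-power")[0][0])
        threshold = PLANT.ambient + 0.2 * (cfg.setpoint - PLANT.ambient)
        assert res.series.value[first_pid] >= threshold
        # the previous controller sample was still below the threshold
        prev_sample = max(0, first_pid - int(cfg.duty_period))
        assert res.series.value[prev_sample] < threshold

    def test_voltage_bounded_and_off_above_setpoint(self):
        cfg = TempControlConfig(setpoint=35.0)
        res = simulate_temperature(PLANT, cfg, t_end=7200.0, dt=1.0)
        v = res.series.actuator
        assert np.all((v >= 0.0) & (v <= cfg.v_line))
        off_mask = res.series.mode == "off"
        assert np.all(v[off_mask] == 0.0)


class TestPHChemistry:
    def test_charge_balance_round_trip(self):
        for ph in (2.0, 4.15, 7.0, 9.3, 12.0):
            c = strong_acid_concentration_from_ph(ph)
            assert ph_from_strong_acid_concentration(c) == pytest.approx(ph, abs=1e-12)

    def test_single_acid_pulse_into_neutral_litre(self):
        # 3 drops x 50 uL x 0.47 M into 1 L at pH 7
        c = 3 * 5e-5 * 0.47 / 1.0
        assert ph_from_strong_acid_concentration(c) == pytest.approx(4.15, abs=0.01)


class TestPHLoop:
    ACID = PHPlant(band=(4.5, 5.5), initial_ph=7.0, noise_sd=0.0)

    def test_starts_inside_band_no_drops(self):
        plant = dataclasses.replace(self.ACID, initial_ph=5.0)
        res = simulate_ph(plant, t_end=60.0, dt=0.5, seed=0)
        assert res.drops_acid == 0 and res.drops_base == 0
        assert np.allclose(res.series.value, 5.0)

    def test_acid_scenario_terminates_inside_band(self):
        res = simulate_ph(self.ACID, t_end=600.0, dt=0.5, seed=0)
        assert self.ACID.band[0] < res.final_ph < self.ACID.band[1]
        assert res.drops_acid > 0

    def test_alkaline_scenario_terminates_inside_band(self):
        plant = dataclasses.replace(self.ACID, band=(7.0, 8.0), initial_ph=5.0)
        res = simulate_ph(plant, t_end=600.0, dt=0.5, seed=0)
        assert 7.0 < res.final_ph < 8.0

    def test_mole_bookkeeping_conserved(self):
        res = simulate_ph(self.ACID, t_end=600.0, dt=0.5, seed=0)
        assert res.moles_acid == pytest.approx(res.drops_acid * 5e-5 * 0.47, rel=1e-12)
        assert res.moles_base == pytest.approx(res.drops_base * 5e-5 * 0.5, rel=1e-12)
        # and the final pH is exactly what the net added moles imply
        c0 = strong_acid_concentration_from_ph(self.ACID.initial_ph) * self.ACID.volume
        volume = self.ACID.volume + (res.drops_acid + res.drops_base) * 5e-5
        c = (c0 + res.moles_acid - res.moles_base) / volume
        assert res.final_ph == pytest.approx(ph_from_strong_acid_concentration(c), abs=1e-9)

    def test_ph_constant_between_pulses(self):
        res = simulate_ph(self.ACID, t_end=120.0, dt=0.5, seed=0)
        quiet = res.series.actuator == 0
        # wherever no drop fell, the well-mixed pH cannot change
        dv = np.diff(res.series.value)
        assert np.all(dv[quiet[1:]] == 0.0)

    def test_deterministic_for_fixed_seed(self):
        plant = dataclasses.replace(self.ACID, noise_sd=0.05)
        r1 = simulate_ph(plant, t_end=300.0, dt=0.5, seed=7)
        r2 = simulate_ph(plant, t_end=300.0, dt=0.5, seed=7)
        assert np.array_equal(r1.series.value, r2.series.value)


class TestStirrerLoop:
    @pytest.mark.parametrize("setpoint", [25.0, 50.0, 100.0])
    def test_holds_ten_rpm_band(self, setpoint):
        plant = StirrerPlant(setpoint=setpoint, noise_sd=0.0)
        res = simulate_stirrer(plant, t_end=20.0, dt=0.01)
        assert abs(res.series.value[-1] - setpoint) <= 10.0
        assert res.band_occupancy == 1.0

    def test_zero_setpoint_stays_at_rest(self):
        res = simulate_stirrer(StirrerPlant(setpoint=0.0, noise_sd=0.0), t_end=5.0, dt=0.01)
        assert np.all(res.series.value == 0.0)

    def test_bit_identical_for_same_seed(self):
        p = StirrerPlant(setpoint=50.0, noise_sd=2.0, seed=11)
        r1 = simulate_stirrer(p, t_end=10.0, dt=0.01)
        r2 = simulate_stirrer(p, t_end=10.0, dt=0.01)
        assert np.array_equal(r1.series.value, r2.series.value)
        assert np.array_equal(r1.series.actuator, r2.series.actuator)

    def test_seed_changes_noisy_trajectory(self):
        r1 = simulate_stirrer(StirrerPlant(setpoint=50.0, seed=1), t_end=5.0, dt=0.01)
        r2 = simulate_stirrer(StirrerPlant(setpoint=50.0, seed=2), t_end=5.0, dt=0.01)
        assert not np.array_equal(r1.series.value, r2.series.value)
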