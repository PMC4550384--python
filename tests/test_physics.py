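"""Dielectric heating, field reconstruction, lumped thermal dynamics and
the set-point controller."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rfivm import physics
from rfivm.physics import (
    ComplexPermittivity,
    ControllerConfig,
    ControllerStalledError,
    InvalidGridError,
    InvalidMaterialError,
    InvalidScheduleError,
    MaterialThermal,
    NoOverlapError,
    PowerSchedule,
    TemperatureTrace,
    VoltageGrid,
    compare_traces,
    efield_from_voltage,
    heating_rate,
    setpoint_controller,
    simulate_temperature,
)

WATER_LIKE = MaterialThermal(density=1000.0, specific_heat=4186.0)
PERM = ComplexPermittivity(eps_real=90.0, eps_imag=70.0, frequency_hz=13.56e6)


class TestHeatingRate:
    def test_zero_field_gives_zero(self):
        for flag in (True, False):
            assert heating_rate(PERM, 0.0, WATER_LIKE, include_omega=flag) == 0.0

    def test_pinned_value_with_omega(self):
        # omega * eps0 * eps'' * E^2 / (2 rho c_p) hand-evaluated once for
        # eps''=70, E=15 kV/m, water-like tissue at 13.56 MHz.
        got = heating_rate(PERM, 15e3, WATER_LIKE, include_omega=True)
        assert got == pytest.approx(1.4191569029055378, rel=1e-12)

    def test_pinned_value_printed_form(self):
        got = heating_rate(PERM, 15e3, WATER_LIKE, include_omega=False)
        assert got == pytest.approx(1.6656772575250834e-08, rel=1e-12)

    @given(e=st.floats(1.0, 1e5), scale=st.floats(0.1, 10.0))
    def test_quadratic_in_field(self, e, scale):
        base = heating_rate(PERM, e, WATER_LIKE)
        assert heating_rate(PERM, scale * e, WATER_LIKE) == pytest.approx(
            scale ** 2 * base, rel=1e-12
        )

    def test_linear_in_loss_factor_and_rho_cp_tradeoff(self):
        base = heating_rate(PERM, 1e4, WATER_LIKE)
        doubled = ComplexPermittivity(PERM.eps_real, 2 * PERM.eps_imag,
                                      PERM.frequency_hz)
        assert heating_rate(doubled, 1e4, WATER_LIKE) == pytest.approx(2 * base)
        traded = MaterialThermal(2 * WATER_LIKE.density,
                                 WATER_LIKE.specific_heat / 2)
        assert heating_rate(PERM, 1e4, traded) == pytest.approx(base)

    def test_invalid_material_rejected(self):
        with pytest.raises(InvalidMaterialError):
            MaterialThermal(density=-1.0, specific_heat=4186.0)
        with pytest.raises(InvalidMaterialError):
            MaterialThermal(density=1000.0, specific_heat=0.0)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            heating_rate(PERM, -1.0, WATER_LIKE)


def brute_force_gradient(values: np.ndarray, spacing: float) -> list[np.ndarray]:
    """Per-node difference quotients: central interior, one-sided edges."""
    out = []
    for axis in range(2):
        g = np.empty_like(values, dtype=float)
        v = np.moveaxis(values, axis, 0)
        gm = np.moveaxis(g, axis, 0)
        n = v.shape[0]
        for i in range(n):
            if i == 0:
                gm[i] = (v[1] - v[0]) / spacing
            elif i == n - 1:
                gm[i] = (v[n - 1] - v[n - 2]) / spacing
            else:
                gm[i] = (v[i + 1] - v[i - 1]) / (2 * spacing)
        out.append(g)
    return out


class TestEfieldFromVoltage:
    def test_constant_potential_zero_field(self):
        grid = VoltageGrid(values=np.full((4, 6), 3.7), spacing=0.01)
        fld = efield_from_voltage(grid)
        assert np.all(fld.magnitude == 0)

    def test_linear_potential_uniform_field(self):
        # V drops 1 V per 0.01 m node along x -> E_x = +100 V/m everywhere.
        cols = np.arange(8, dtype=float)
        grid = VoltageGrid(values=np.tile(-cols, (5, 1)), spacing=0.01)
        fld = efield_from_voltage(grid)
        np.testing.assert_allclose(fld.components[1], 100.0)
        np.testing.assert_allclose(fld.components[0], 0.0)
        np.testing.assert_allclose(fld.magnitude, 100.0)

    def test_random_grid_matches_difference_quotient_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(size=(5, 5)) * 50
            grid = VoltageGrid(values=values, spacing=0.01)
            fld = efield_from_voltage(grid)
            oracle = brute_force_gradient(values, 0.01)
            for got, exp in zip(fld.components, oracle):
                np.testing.assert_allclose(got, -exp, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(
                fld.magnitude, np.hypot(-oracle[0], -oracle[1]), rtol=1e-12
            )

    def test_affine_potential_constant_field(self, rng):
        rows, cols = np.meshgrid(np.arange(6), np.arange(7), indexing="ij")
        values = 2.5 * rows - 1.5 * cols + 4.0
        fld = efield_from_voltage(VoltageGrid(values=values, spacing=0.02))
        assert np.ptp(fld.magnitude) < 1e-12

    def test_invalid_grids_rejected(self):
        with pytest.raises(InvalidGridError):
            VoltageGrid(values=np.zeros((2, 2)), spacing=0.0)
        with pytest.raises(InvalidGridError):
            VoltageGrid(values=np.zeros((1, 5)), spacing=0.01)

    def test_csv_round_trip(self, tmp_path, rng):
        grid = VoltageGrid(values=rng.normal(size=(4, 5)), spacing=0.01)
        grid.to_csv(tmp_path / "v.csv")
        back = VoltageGrid.from_csv(tmp_path / "v.csv")
        assert back.spacing == grid.spacing
        np.testing.assert_allclose(back.values, grid.values)


class TestSimulateTemperature:
    def test_zero_power_at_ambient_is_constant(self):
        sched = PowerSchedule(times=[0.0, 100.0], power=[0.0, 0.0])
        trace = simulate_temperature(sched, cooling_coeff=0.01,
                                     ambient_c=30.0, t0_c=30.0)
        np.testing.assert_allclose(trace.probe(0), 30.0)

    def test_full_power_no_cooling_is_exactly_linear(self):
        sched = PowerSchedule(times=[0.0, 10.0], power=[200.0, 200.0])
        trace = simulate_temperature(sched, field_at_max_power=15e3,
                                     cooling_coeff=0.0, t0_c=30.0, dt=0.1)
        hr = heating_rate(physics.TUMOR_PERMITTIVITY, 15e3, physics.TUMOR_TISSUE)
        np.testing.assert_allclose(trace.probe(0), 30.0 + hr * trace.times,
                                   rtol=1e-9)

    def test_step_schedule_matches_fine_step_reference(self):
        sched = PowerSchedule(times=[0.0, 60.0, 120.0, 200.0],
                              power=[90.0, 0.0, 150.0, 0.0])
        kwargs = dict(field_at_max_power=12e3, cooling_coeff=0.02,
                      ambient_c=30.0, t0_c=32.0)
        coarse = simulate_temperature(sched, dt=0.1, **kwargs)
        fine = simulate_temperature(sched, dt=0.01, **kwargs)
        aligned = np.interp(coarse.times, fine.times, fine.probe(0))
        assert np.max(np.abs(coarse.probe(0) - aligned)) < 0.05

    def test_cooling_decays_monotonically_toward_ambient(self):
        sched = PowerSchedule(times=[0.0, 400.0], power=[0.0, 0.0])
        trace = simulate_temperature(sched, cooling_coeff=0.01,
                                     ambient_c=30.0, t0_c=45.0)
        temps = trace.probe(0)
        assert np.all(np.diff(temps) < 0)
        assert temps.min() >= 30.0

    def test_temperature_never_below_floor(self):
        sched = PowerSchedule(times=[0.0, 50.0, 300.0], power=[90.0, 0.0, 0.0])
        trace = simulate_temperature(sched, cooling_coeff=0.02,
                                     ambient_c=28.0, t0_c=30.0)
        assert trace.probe(0).min() >= 28.0 - 1e-9

    def test_empty_schedule_rejected(self):
        with pytest.raises(InvalidScheduleError):
            PowerSchedule(times=[], power=[])

    def test_schedule_and_trace_csv_round_trip(self, tmp_path):
        sched = PowerSchedule(times=[0.0, 5.0], power=[90.0, 0.0])
        sched.to_csv(tmp_path / "p.csv")
        back = PowerSchedule.from_csv(tmp_path / "p.csv")
        np.testing.assert_allclose(back.times, sched.times)
        np.testing.assert_allclose(back.power, sched.power)
        trace = TemperatureTrace(times=[0.0, 1.0, 2.0],
                                 temperature=[[30, 31], [32, 31.5], [33, 32]],
                                 probe_labels=("probe1", "probe2"))
        trace.to_csv(tmp_path / "t.csv")
        back_t = TemperatureTrace.from_csv(tmp_path / "t.csv")
        assert back_t.probe_labels == trace.probe_labels
        np.testing.assert_allclose(back_t.temperature, trace.temperature)


class TestSetpointController:
    def run_default(self, **kwargs):
        return setpoint_controller(ControllerConfig(), dt=0.1,
                                   cooling_coeff=0.005, **kwargs)

    def test_three_episodes_with_decreasing_peaks(self):
        cfg = ControllerConfig()
        schedule, trace = self.run_default()
        on_times = schedule.times[schedule.power > 0]
        assert on_times.size == len(cfg.setpoints)
        temps = trace.probe(0)
        hr_step = 0.1 * heating_rate(
            physics.TUMOR_PERMITTIVITY, 15e3, physics.TUMOR_TISSUE
        ) * cfg.on_power / schedule.max_power
        # each episode's peak hits its setpoint within one Euler step
        off_times = schedule.times[schedule.power == 0]
        for off_t, sp in zip(off_times, cfg.setpoints):
            idx = np.searchsorted(trace.times, off_t)
            assert sp <= temps[idx] <= sp + hr_step + 1e-9

    def test_resume_happens_inside_band(self):
        cfg = ControllerConfig()
        schedule, trace = self.run_default()
        resume_times = schedule.times[1:][schedule.power[1:] > 0]
        assert resume_times.size == len(cfg.setpoints) - 1
        for t in resume_times:
            idx = np.searchsorted(trace.times, t)
            assert cfg.resume_band[0] <= trace.probe(0)[idx] <= cfg.resume_band[1]

    def test_episode_peaks_strictly_decreasing_in_time(self):
        schedule, trace = self.run_default()
        temps = trace.probe(0)
        off_idx = [int(np.searchsorted(trace.times, t))
                   for t in schedule.times[schedule.power == 0]]
        peaks = temps[off_idx]
        assert np.all(np.diff(peaks) < 0)
        assert np.all(np.diff(off_idx) > 0)

    def test_setpoint_already_reached_terminates_immediately(self):
        cfg = ControllerConfig(setpoints=(30.0,), resume_band=(27.0, 29.0))
        schedule, trace = setpoint_controller(cfg, t0_c=30.0, dt=0.1)
        assert trace.times.size == 1  # zero-length heating episode
        assert np.all(schedule.power == 0)

    def test_ambient_above_resume_band_stalls(self):
        cfg = ControllerConfig(setpoints=(45.0, 43.0), resume_band=(29.0, 31.0))
        with pytest.raises(ControllerStalledError):
            setpoint_controller(cfg, ambient_c=35.0, t0_c=35.0,
                                cooling_coeff=0.005, dt=0.1, max_steps=200_000)

    def test_multi_probe_resume_requires_all_probes(self):
        # second probe sees a weaker field, heats/cools with the same
        # cooling constant, so resume is still reached; the trace carries
        # both probes.
        cfg = ControllerConfig()
        schedule, trace = setpoint_controller(
            cfg, field_at_max_power=[15e3, 10e3], cooling_coeff=0.005, dt=0.1
        )
        assert trace.n_probes == 2
        assert trace.probe(1).max() < trace.probe(0).max()


class TestCompareTraces:
    def test_identical_traces_zero(self):
        t = TemperatureTrace(times=np.linspace(0, 10, 21),
                             temperature=np.linspace(30, 45, 21))
        cmp = compare_traces(t, t)
        assert cmp.mean_abs_dev == 0.0 and cmp.max_abs_dev == 0.0

    def test_constant_offset_recovered(self):
        times = np.linspace(0, 100, 101)
        a = TemperatureTrace(times=times, temperature=30 + 0.1 * times)
        b = TemperatureTrace(times=times, temperature=30.3 + 0.1 * times)
        cmp = compare_traces(a, b)
        assert cmp.mean_abs_dev == pytest.approx(0.3)
        assert cmp.max_abs_dev == pytest.approx(0.3)
        flipped = compare_traces(b, a)
        assert flipped.mean_abs_dev == cmp.mean_abs_dev

    def test_gaussian_noise_gives_half_normal_mean_deviation(self, rng):
        # |N(0, sigma)| has mean sigma*sqrt(2/pi)
        times = np.arange(5000.0)
        base = 35.0 + 0.001 * times
        sigma = 0.1
        noisy = TemperatureTrace(times=times,
                                 temperature=base + rng.normal(0, sigma, 5000))
        cmp = compare_traces(TemperatureTrace(times=times, temperature=base),
                             noisy)
        assert cmp.mean_abs_dev == pytest.approx(sigma * np.sqrt(2 / np.pi),
                                                 abs=0.005)

    def test_disjoint_supports_rejected(self):
        a = TemperatureTrace(times=[0.0, 1.0], temperature=[30.0, 31.0])
        b = TemperatureTrace(times=[5.0, 6.0], temperature=[30.0, 31.0])
        with pytest.raises(NoOverlapError):
            compare_traces(a, b)
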