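"""Two-mass mechanics: Green's-function solver vs closed forms and ODE oracle."""

import numpy as np
import pytest

from vcapsim.mechanics import (
    MechParams,
    NoStimulusError,
    UnsupportedDampingError,
    force_epithelium,
    force_otoconia,
    greens_kernel,
    natural_frequencies,
    simulate_mechanics,
    solve_sdof,
    solve_sdof_reference,
    transfer_crossover,
    transfer_functions,
)
from vcapsim.stimuli import PulseSpec, TimeGrid, constant_jerk_pulse, mg_to_ms2, sine_burst
from vcapsim.waveform import GridError, Waveform


def rel_rms(a, b):
    return np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))


def step_forcing(grid, amp=1.0, onset=1e-3):
    return Waveform(grid.t_start, grid.dt,
                    np.where(grid.t >= onset, amp, 0.0), "m/s^2")


class TestGreensKernel:
    def test_zero_at_origin_unit_slope(self, grid, mech):
        g = greens_kernel(mech.omega1, mech.zeta1, grid)
        assert g.values[0] == 0.0
        # G'(0+) = 1
        assert (g.values[1] - g.values[0]) / grid.dt == pytest.approx(1.0, rel=2e-2)

    def test_overdamped_rejected(self, grid, mech):
        with pytest.raises(UnsupportedDampingError):
            greens_kernel(mech.omega1, 1.2, grid)

    def test_kernel_rings_at_damped_frequency(self, grid, mech):
        g = greens_kernel(mech.omega1, mech.zeta1, grid)
        # zero crossings spaced by half the damped period (496 Hz)
        sign_changes = np.nonzero(np.diff(np.sign(g.values[1:])))[0]
        half_period = np.mean(np.diff(sign_changes)) * grid.dt
        f_d = 1.0 / (2 * half_period)
        assert f_d == pytest.approx(520.0 * np.sqrt(1 - 0.3**2), rel=5e-3)


class TestSolveSdof:
    def test_zero_forcing(self, grid, mech):
        f = Waveform(0.0, grid.dt, np.zeros(grid.n), "m/s^2")
        assert np.allclose(solve_sdof(f, mech.omega1, mech.zeta1).values, 0.0)

    def test_step_steady_state(self, grid, mech):
        f = step_forcing(grid, amp=2.0)
        x = solve_sdof(f, mech.omega1, mech.zeta1)
        assert x.values[-1] == pytest.approx(2.0 / mech.omega1**2, rel=1e-3)

    @pytest.mark.parametrize("f_stim", [100.0, 520.0, 1200.0])
    def test_sine_amplitude_matches_frequency_response(self, mech, f_stim):
        grid = TimeGrid(0.0, 0.1, 1e-5)
        w = 2 * np.pi * f_stim
        f = Waveform(0.0, grid.dt, np.sin(w * grid.t), "m/s^2")
        x = solve_sdof(f, mech.omega1, mech.zeta1)
        gain = abs(1.0 / (mech.omega1**2 - w**2 + 2j * mech.zeta1 * mech.omega1 * w))
        steady = x.values[grid.n // 2:]
        assert np.max(np.abs(steady)) == pytest.approx(gain, rel=5e-3)

    @pytest.mark.parametrize("forcing", ["step", "sine_burst", "jerk_pulse"])
    def test_oracle_equivalence(self, mech, forcing):
        """Green's-function solution vs 4th-order ODE stepping, <0.1% rel RMS."""
        grid = TimeGrid(0.0, 0.03, 1e-5)
        if forcing == "step":
            f = step_forcing(grid)
        elif forcing == "sine_burst":
            f = sine_burst(PulseSpec("sine_burst", 1.0, 1e-3, frequency=1000.0,
                                     n_cycles=5), grid)
        else:
            _, f = constant_jerk_pulse(PulseSpec("constant_jerk", 40.0, 1e-3), grid)
        for omega, zeta in ((mech.omega1, mech.zeta1), (mech.omega2, mech.zeta2)):
            x_green = solve_sdof(f, omega, zeta)
            x_rk4 = solve_sdof_reference(f, omega, zeta)
            assert rel_rms(x_green.values, x_rk4.values) < 1e-3

    def test_oracle_rejects_coarse_grid(self, mech):
        grid = TimeGrid(0.0, 0.01, 1e-4)
        f = step_forcing(grid)
        with pytest.raises(ValueError, match="coarse"):
            solve_sdof_reference(f, mech.omega2, mech.zeta2)


class TestForcing:
    def test_epithelium_forcing_terms(self, grid, mech):
        a = step_forcing(grid, amp=1.0, onset=0.0)
        f2 = force_epithelium(a, None, mech)
        assert np.allclose(f2.values, -1.0)  # beta2 = 1
        f2 = force_epithelium(None, a, mech)
        assert np.allclose(f2.values, -mech.alpha)  # alpha = 0.3
        with pytest.raises(NoStimulusError):
            force_epithelium(None, None, mech)

    def test_otoconia_forcing_static_offset(self, grid, mech):
        u = 1e-6
        x2 = Waveform(0.0, grid.dt, np.full(grid.n, u), "m")
        f1 = force_otoconia(None, x2, mech)
        assert np.allclose(f1.values, mech.omega1**2 * u)

    def test_grid_mismatch(self, grid, mech):
        a = step_forcing(grid)
        b = Waveform(0.0, grid.dt / 2, a.values, "m/s^2")
        with pytest.raises(GridError):
            force_epithelium(a, b, mech)


class TestSimulateMechanics:
    def test_static_shear_closed_form(self, mech):
        """Constant acceleration: theta_ss = atan(-a0/(omega1^2 h))."""
        grid = TimeGrid(0.0, 0.05, 1e-5)
        a0 = mg_to_ms2(2.6)
        ramp = np.clip(grid.t / 5e-3, 0.0, 1.0)  # gentle ramp to constant
        a = Waveform(0.0, grid.dt, a0 * ramp, "m/s^2")
        res = simulate_mechanics(bcv_accel=a, p=mech)
        expected = np.arctan(-a0 / (mech.omega1**2 * mech.h))
        assert res.theta.values[-1] == pytest.approx(expected, rel=1e-3)

    def test_zero_stimulus_errors(self, mech):
        with pytest.raises(NoStimulusError):
            simulate_mechanics(p=mech)

    def test_linearity_and_superposition(self, mech):
        grid = TimeGrid(0.0, 0.02, 1e-5)
        s1 = sine_burst(PulseSpec("sine_burst", 1e-2, 1e-3, frequency=500.0,
                                  n_cycles=2), grid)
        s2 = step_forcing(grid, amp=5e-3)
        r1 = simulate_mechanics(bcv_accel=s1, p=mech)
        r2 = simulate_mechanics(bcv_accel=s2, p=mech)
        r12 = simulate_mechanics(bcv_accel=s1 + s2, p=mech)
        lhs = r12.x1.values - r12.x2.values
        rhs = (r1.x1.values - r1.x2.values) + (r2.x1.values - r2.x2.values)
        assert np.max(np.abs(lhs - rhs)) < 1e-10 * np.max(np.abs(rhs))

    def test_doubling_doubles_small_angle_response(self, mech):
        grid = TimeGrid(0.0, 0.02, 1e-5)
        s = sine_burst(PulseSpec("sine_burst", 1e-3, 1e-3, frequency=500.0,
                                 n_cycles=2), grid)
        r1 = simulate_mechanics(bcv_accel=s, p=mech)
        r2 = simulate_mechanics(bcv_accel=2.0 * s, p=mech)
        assert np.allclose(r2.x1.values, 2 * r1.x1.values, rtol=1e-9, atol=1e-30)
        ratio = np.max(np.abs(r2.theta.values)) / np.max(np.abs(r1.theta.values))
        assert ratio == pytest.approx(2.0, rel=1e-4)  # small-angle regime

    def test_causality(self, mech):
        grid = TimeGrid(0.0, 0.02, 1e-5)
        s = sine_burst(PulseSpec("sine_burst", 1e-2, 1e-3, frequency=500.0,
                                 n_cycles=2, onset=5e-3), grid)
        res = simulate_mechanics(bcv_accel=s, p=mech)
        pre = grid.t < 5e-3
        # FFT-convolution round-off only: zero to machine precision rel. to peak
        assert np.max(np.abs(res.x1.values[pre])) < 1e-14 * np.max(np.abs(res.x1.values))
        assert np.max(np.abs(res.theta.values[pre])) < 1e-14 * np.max(np.abs(res.theta.values))

    def test_theta_bounded_for_blast_scale_input(self, mech):
        grid = TimeGrid(0.0, 0.02, 1e-5)
        s = step_forcing(grid, amp=5e4)  # absurdly strong
        res = simulate_mechanics(bcv_accel=s, p=mech)
        assert np.max(np.abs(res.theta.values)) < np.pi / 2
        # the linear displacement keeps growing even though theta saturates
        assert np.max(np.abs(res.x1.values - res.x2.values)) > 10 * mech.h


class TestNaturalFrequencies:
    def test_default_modes(self, mech):
        lo, hi = natural_frequencies(mech)
        assert lo == pytest.approx(520.0 * np.sqrt(1 - 0.09), rel=1e-9)  # 496 Hz
        assert lo < hi

    def test_undamped_limit(self):
        p = MechParams(zeta1=1e-9, zeta2=1e-9)
        lo, hi = natural_frequencies(p)
        assert lo == pytest.approx(520.0, rel=1e-9)
        assert hi == pytest.approx(1240.0, rel=1e-9)


class TestTransferFunctions:
    def test_jerk_gain_flat_at_low_frequency(self, mech):
        g_a, g_j = transfer_functions(mech, [10.0])
        dc = mech.beta1 / (mech.omega1**2 * mech.h)
        assert abs(g_j[0]) == pytest.approx(dc, rel=0.05)

    def test_crossover_near_530(self, mech):
        fc = transfer_crossover(mech)
        assert fc == pytest.approx(530.0, rel=0.03)

    def test_analytic_gain_matches_time_domain_simulation(self, mech):
        """FFT-free cross-check: steady-state sine response vs analytic gain."""
        for f_stim in (200.0, 530.0, 1000.0):
            grid = TimeGrid(0.0, 0.1, 1e-5)
            w = 2 * np.pi * f_stim
            a = Waveform(0.0, grid.dt, 1e-4 * np.sin(w * grid.t), "m/s^2")
            res = simulate_mechanics(bcv_accel=a, p=mech)
            steady = res.theta_dot.values[grid.n // 2:]
            g_a, _ = transfer_functions(mech, [f_stim])
            assert np.max(np.abs(steady)) == pytest.approx(
                1e-4 * abs(g_a[0]), rel=0.02
            )
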