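"""Integration accuracy, steady-state detection, delays and peaks."""

import numpy as np
import pytest

from psfopt import (
    SolverProfile,
    Trajectory,
    delay_ec90,
    detect_steady_state,
    find_peak,
    run_to_steady,
    simulate,
)
from psfopt.simulate import DelayError, REFERENCE_PROFILE


def analytic_trajectory(times, values, name="X"):
    v = np.asarray(values, dtype=float)
    return Trajectory(np.asarray(times, float), v[:, None], [name], 0.0)


class TestSimulate:
    def test_first_order_decay_matches_closed_form(self, toy_conversion):
        """A -> B at kcat=0.1/s: A(t) = 100*exp(-0.1 t) to <0.1%."""
        traj = simulate(toy_conversion, clamp=0.0, t_end=60.0)
        expected = 100.0 * np.exp(-0.1 * traj.times)
        err = np.abs(traj.series("A") - expected) / 100.0
        assert err.max() < 1e-3

    def test_clamped_binding_reaches_kd_half_occupancy(self, toy_binding):
        """With A clamped at its Kd (333.33 nM), half of B ends up bound."""
        kd = 0.1 / 0.0003
        traj, ss = run_to_steady(toy_binding, clamp=kd)
        assert ss.converged
        bound = ss.ss_values[toy_binding.species_index("C")]
        assert bound == pytest.approx(50.0, rel=1e-3)

    def test_equilibrated_baseline_stays_near_flat(self, default_model):
        """Continuing from a detected steady state keeps every species
        within the 2%/100 s envelope (the PKA holoenzyme pool relaxes on a
        time scale of days, so exact equilibrium is not the reference)."""
        traj0, ss0 = run_to_steady(default_model, clamp=0.0)
        assert ss0.converged
        traj = simulate(
            default_model, clamp=0.0, t_end=100.0, from_state=traj0.final_state
        )
        drift = np.abs(traj.states[-1] - traj.states[0])
        scale = np.maximum(np.abs(traj.states[0]), 1e-6)
        assert np.max(drift / scale) < 0.02

    def test_step_up_raises_output(self, default_model):
        traj, ss = run_to_steady(default_model, clamp=10.0)
        traj2, ss2 = run_to_steady(
            default_model, clamp=20.0, from_state=traj.final_state
        )
        i = default_model.species_index("pVASP")
        assert ss2.ss_values[i] > ss.ss_values[i]

    def test_invalid_arguments(self, default_model):
        with pytest.raises(ValueError):
            simulate(default_model, clamp=10.0, t_end=0.0)
        with pytest.raises(ValueError):
            simulate(default_model, clamp=-1.0, t_end=10.0)

    def test_nonnegative_states(self, default_model):
        traj = simulate(default_model, clamp=500.0, t_end=2000.0)
        assert traj.states.min() >= 0.0

    def test_tolerance_robustness(self, default_model):
        """Halving the integrator tolerances moves steady states by <0.1%."""
        tight = SolverProfile(rtol=0.5e-8, atol=0.5e-6)
        _, ss_a = run_to_steady(default_model, clamp=50.0)
        _, ss_b = run_to_steady(default_model, clamp=50.0, profile=tight)
        rel = np.abs(ss_a.ss_values - ss_b.ss_values) / np.maximum(
            np.abs(ss_a.ss_values), 1e-3
        )
        assert rel.max() < 1e-3


class TestSteadyStateDetection:
    def test_constant_trajectory_steady_at_zero(self):
        t = np.arange(0, 301.0, 10.0)
        traj = analytic_trajectory(t, np.full_like(t, 7.0))
        ss = detect_steady_state(traj)
        assert ss.converged and ss.t_ss == 0.0

    def test_exponential_approach_matches_brute_force_scan(self):
        """C(t)=100(1-exp(-t/100)): earliest t with <2% change over 100 s,
        cross-checked against a dense scan of the closed form."""
        t = np.arange(0.0, 2001.0, 1.0)
        c = 100.0 * (1.0 - np.exp(-t / 100.0))
        traj = analytic_trajectory(t, c)
        ss = detect_steady_state(traj)
        # independent oracle: dense scan of the analytic expression
        tt = np.arange(0.0, 1901.0, 1.0)
        ct = 100.0 * (1.0 - np.exp(-tt / 100.0))
        ct100 = 100.0 * (1.0 - np.exp(-(tt + 100.0) / 100.0))
        ok = np.abs(ct100 - ct) / np.maximum(ct, 1e-6) < 0.02
        t_expected = tt[np.argmax(ok)]
        assert ss.converged
        assert ss.t_ss == pytest.approx(t_expected, abs=1.0)

    def test_oscillation_never_converges(self):
        t = np.arange(0.0, 1001.0, 1.0)
        traj = analytic_trajectory(t, 50.0 + 30.0 * np.sin(2 * np.pi * t / 180.0))
        ss = detect_steady_state(traj)
        assert not ss.converged and ss.t_ss is None

    def test_short_trajectory_rejected(self):
        t = np.arange(0.0, 50.0, 1.0)
        with pytest.raises(ValueError, match="100"):
            detect_steady_state(analytic_trajectory(t, np.ones_like(t)))


class TestDelay:
    def test_already_at_steady_state_gives_zero(self):
        t = np.arange(0.0, 200.0, 1.0)
        traj = analytic_trajectory(t, np.full_like(t, 42.0))
        assert delay_ec90(traj, "X", baseline=10.0, ss_value=42.0) == 0.0

    def test_first_order_delay_is_tau_ln10(self):
        """1-exp(-t/tau) crosses 90% at tau*ln(10) (=230.26 s for tau=100)."""
        t = np.arange(0.0, 1500.0, 0.5)
        tau = 100.0
        traj = analytic_trajectory(t, 80.0 * (1 - np.exp(-t / tau)))
        d = delay_ec90(traj, "X", baseline=0.0, ss_value=80.0)
        assert d == pytest.approx(tau * np.log(10.0), rel=5e-3)

    @pytest.mark.parametrize("tau", [20.0, 50.0, 100.0, 300.0])
    def test_delay_monotone_in_tau(self, tau):
        t = np.arange(0.0, 5000.0, 1.0)
        d = delay_ec90(
            analytic_trajectory(t, 1 - np.exp(-t / tau)), "X", 0.0, 1.0
        )
        d2 = delay_ec90(
            analytic_trajectory(t, 1 - np.exp(-t / (2 * tau))), "X", 0.0, 1.0
        )
        assert d2 > d

    def test_decreasing_response_handled(self):
        t = np.arange(0.0, 1000.0, 1.0)
        traj = analytic_trajectory(t, 100.0 * np.exp(-t / 50.0))
        d = delay_ec90(traj, "X", baseline=100.0, ss_value=0.0)
        assert d == pytest.approx(50.0 * np.log(10.0), rel=5e-3)

    def test_never_crossing_raises_delay_error(self):
        t = np.arange(0.0, 500.0, 1.0)
        traj = analytic_trajectory(t, 0.5 * (1 - np.exp(-t / 50.0)))
        with pytest.raises(DelayError):
            delay_ec90(traj, "X", baseline=0.0, ss_value=2.0)


class TestPeak:
    def test_calculus_oracle_peak(self):
        """C(t) = t*exp(1-t) peaks at exactly (t=1, C=1)."""
        t = np.linspace(0.0, 10.0, 4001)
        traj = analytic_trajectory(t, t * np.exp(1.0 - t))
        peak, t_peak, has_tr = find_peak(traj, "X", ss_value=0.0, baseline=0.0)
        assert peak == pytest.approx(1.0, abs=1e-4)
        assert t_peak == pytest.approx(1.0, abs=5e-3)
        assert has_tr

    def test_monotone_rise_has_no_transient(self):
        t = np.arange(0.0, 500.0, 1.0)
        traj = analytic_trajectory(t, 60.0 * (1 - np.exp(-t / 40.0)))
        peak, _, has_tr = find_peak(traj, "X", ss_value=60.0, baseline=0.0)
        assert not has_tr
        assert peak == pytest.approx(traj.series("X")[-1])

    def test_peak_and_steady_state_agree_on_plateau(self, default_model):
        traj, ss = run_to_steady(default_model, clamp=0.0)
        traj2, ss2 = run_to_steady(
            default_model, clamp=100.0, from_state=traj.final_state
        )
        i = default_model.species_index("pVASP")
        C0, Ct = ss.ss_values[i], ss2.ss_values[i]
        peak, _, has_tr = find_peak(traj2, "pVASP", Ct, baseline=C0)
        if not has_tr:
            assert abs(peak - Ct) <= 0.05 * abs(Ct - C0)
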