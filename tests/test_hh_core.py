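"""Membrane model: currents, gating kinetics, integrator behaviour."""

import numpy as np
import pytest

from mnb1 import (
    MembraneState,
    NeuronParams,
    SimConfig,
    current_drive,
    gating_rates,
    gating_steady_states,
    ionic_currents,
    resting_state,
    simulate,
    step_heun,
)
from mnb1.hh_core import _derivatives
from mnb1.fitting import spike_amplitude


class TestIonicCurrents:
    def test_currents_vanish_at_reversal_potentials(self, neuron):
        s = MembraneState(U=neuron.E_L, m=0.3, h=0.4, n=0.5)
        assert ionic_currents(s, neuron)[2] == 0.0
        s = MembraneState(U=neuron.E_K, m=0.3, h=0.4, n=0.5)
        assert ionic_currents(s, neuron)[1] == 0.0

    def test_leak_current_at_sensilla_rest(self, neuron):
        # g_L (U - E_L) with the fitted passive values at U = -65 mV
        s = MembraneState(U=-65.0, m=0.0, h=0.0, n=0.0)
        _, _, i_l = ionic_currents(s, neuron)
        assert i_l == pytest.approx(5.84 * (-65.0 + 52.26), abs=1e-10)
        assert i_l == pytest.approx(-74.40, abs=0.01)


class TestGatingKinetics:
    def test_singularities_are_removable(self):
        for u_sing, idx in ((-40.0, 0), (-55.0, 4)):
            below = gating_rates(u_sing - 1e-5)[idx]
            at = gating_rates(u_sing)[idx]
            above = gating_rates(u_sing + 1e-5)[idx]
            assert below <= at <= above
            assert above - below < 1e-4

    def test_steady_state_saturation(self):
        m_inf, h_inf, _ = gating_steady_states(80.0)
        assert m_inf > 0.99
        assert h_inf < 0.01

    def test_activation_monotone_in_physiological_range(self):
        u = np.linspace(-80.0, 20.0, 400)
        m_inf, h_inf, n_inf = gating_steady_states(u)
        assert np.all(np.diff(m_inf) > 0)
        assert np.all(np.diff(n_inf) > 0)
        assert np.all(np.diff(h_inf) < 0)

    def test_gate_shift_offsets_the_voltage_axis(self):
        a = gating_steady_states(-50.0, shift=5.0)
        b = gating_steady_states(-45.0, shift=0.0)
        assert np.allclose(a, b)


class TestRestingState:
    def test_long_integration_settles_on_computed_fixed_point(self, neuron, rest):
        """200 ms with no input stays at the root-found rest (two routes)."""
        n_steps = 20000
        cfg = SimConfig(duration=200.0)
        drive = current_drive(np.zeros(n_steps + 1))
        start = MembraneState(U=rest.U - 5.0, m=rest.m, h=rest.h, n=rest.n)
        sim = simulate(neuron, drive, cfg, initial=start)
        assert sim.U[-1] == pytest.approx(rest.U, abs=1e-4)
        dy = _derivatives(
            np.array([sim.U[-1], sim.m[-1], sim.h[-1], sim.n[-1]]), neuron, 0.0
        )
        assert np.all(np.abs(dy) < 1e-5)

    def test_returns_from_subthreshold_perturbation(self, neuron, rest):
        drive = current_drive(np.zeros(10001))
        start = MembraneState(U=rest.U + 6.0, m=rest.m, h=rest.h, n=rest.n)
        sim = simulate(neuron, drive, SimConfig(duration=100.0), initial=start)
        assert sim.U[-1] == pytest.approx(rest.U, abs=1e-3)
        assert np.max(sim.U) < -40.0  # never spikes


class TestHeunStep:
    def test_rest_is_a_fixed_point_of_the_step(self, neuron, rest):
        out = step_heun(rest, neuron, lambda t, u: 0.0, 0.0, 0.01)
        assert out.U == pytest.approx(rest.U, abs=1e-9)

    def test_second_order_accuracy_on_leak_only_membrane(self):
        """Halving dt reduces the error vs the exact exponential ~4x."""
        p = NeuronParams(gbar_Na=0.0, gbar_K=0.0, g_L=2.0, E_L=-52.26)
        u0, dur = -70.0, 1.0

        def run(dt):
            s = MembraneState(U=u0, m=0.0, h=1.0, n=0.0)
            for k in range(int(round(dur / dt))):
                s = step_heun(s, p, lambda t, u: 0.0, k * dt, dt)
            return s.U

        exact = p.E_L + (u0 - p.E_L) * np.exp(-p.g_L * dur / p.C_MN)
        e1 = abs(run(0.02) - exact)
        e2 = abs(run(0.01) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.15)

    def test_kernel_matches_reference_python_stepper(self, neuron):
        """Compiled loop and the pure-Python Heun step agree step for step."""
        n_steps = 500
        rng = np.random.default_rng(1)
        inj = np.abs(rng.normal(20.0, 10.0, n_steps + 1))
        drive = current_drive(inj)
        cfg = SimConfig(duration=n_steps * 0.01)
        sim = simulate(neuron, drive, cfg)
        s = resting_state(neuron)
        for k in range(n_steps):
            s = step_heun(
                s, neuron, lambda t, u, k=k: inj[min(int(round(t / 0.01)), n_steps)],
                k * 0.01, 0.01,
            )
        assert sim.U[-1] == pytest.approx(s.U, abs=1e-9)

    def test_rejects_dt_outside_validated_range(self, neuron, rest):
        with pytest.raises(ValueError):
            step_heun(rest, neuron, lambda t, u: 0.0, 0.0, 0.05)
        with pytest.raises(ValueError):
            SimConfig(dt=0.002, duration=1.0)


class TestSimulate:
    def test_flat_at_rest_without_drive_or_noise(self, neuron, rest):
        sim = simulate(neuron, current_drive(np.zeros(5001)),
                       SimConfig(duration=50.0))
        assert np.allclose(sim.U, rest.U, atol=1e-6)

    def test_noise_reproducible_for_equal_seeds(self, neuron):
        cfg = SimConfig(duration=50.0, sigma_noise=0.1, rng_seed=7)
        a = simulate(neuron, current_drive(np.zeros(5001)), cfg)
        b = simulate(neuron, current_drive(np.zeros(5001)), cfg)
        assert np.array_equal(a.U, b.U)
        c = simulate(neuron, current_drive(np.zeros(5001)),
                     SimConfig(duration=50.0, sigma_noise=0.1, rng_seed=8))
        assert not np.array_equal(a.U, c.U)

    def test_gating_variables_stay_in_unit_interval(self, one_to_one_run):
        _, _, _, sim = one_to_one_run
        for g in (sim.m, sim.h, sim.n):
            assert g.min() >= 0.0
            assert g.max() <= 1.0

    def test_spike_amplitude_monotone_in_sodium_conductance(self):
        """Volley-evoked peak grows with gbar_Na (25-165 mS cm^-2)."""
        amps = [spike_amplitude(g) for g in (25.0, 75.0, 120.0, 165.0)]
        assert np.all(np.diff(amps) > 0)


class TestParamValidation:
    def test_reversal_potential_ordering_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(E_K=-40.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(g_L=-1.0)

    def test_gating_range_enforced(self):
        with pytest.raises(ValueError):
            MembraneState(U=-65.0, m=1.2, h=0.5, n=0.5)
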