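"""Spike detection, locking classification and the experiment protocols."""

import numpy as np
import pytest

from mnb1 import (
    NeuronParams,
    SpikeTrain,
    classify_locking,
    detect_spikes,
    gating_scenarios,
    noise_phase_stability,
    refractory_measurement,
    run_locking,
    sensilla_sweep,
    steady_phase_vs_uin,
    sweep_thresholds,
    volley_from_fraction,
)
from mnb1.protocols import (
    circ_diff,
    circ_mean,
    circ_sd,
    fit_phase_exponential,
    visual_step_response,
)


def make_train(times, period=10.0):
    times = np.asarray(times, float)
    return SpikeTrain(
        times=times,
        phases=(times % period) / period * 100.0,
        amplitudes=np.full(len(times), 40.0),
        period=period,
        rest=-55.7,
    )


class TestCircularStats:
    def test_mean_and_sd_handle_cycle_boundary(self):
        phases = np.array([98.0, 99.0, 1.0, 2.0])
        assert circ_mean(phases) == pytest.approx(0.0, abs=1e-9)
        assert circ_sd(phases) == pytest.approx(np.std([-2, -1, 1, 2]), rel=0.05)

    def test_signed_difference_wraps(self):
        assert circ_diff(2.0, 98.0) == pytest.approx(4.0)
        assert circ_diff(98.0, 2.0) == pytest.approx(-4.0)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self, rest):
        t = np.arange(0.0, 100.0, 0.01)
        train = detect_spikes(t, np.full(t.shape, rest.U), rest=rest.U)
        assert len(train) == 0

    def test_single_evoked_spike_time_and_amplitude(self, neuron, rest, syn):
        from mnb1 import SimConfig, simulate
        from mnb1.synapses import make_drive
        from mnb1.sensory_inputs import VolleySpec

        volley = VolleySpec(n_active_haltere=50, n_active_wing=0, sigma=0.2,
                            period=20.0)
        drive = make_drive(syn, volley, None, 20.0)
        sim = simulate(neuron, drive, SimConfig(duration=20.0))
        train = detect_spikes(sim.t, sim.U, period=20.0, rest=rest.U)
        assert len(train) == 1
        assert train.amplitudes[0] == pytest.approx(np.max(sim.U) - rest.U,
                                                    abs=0.1)
        assert abs(train.times[0] - 5.0) < 3.0  # near the volley

    def test_lockout_merges_close_crossings(self):
        t = np.arange(0.0, 20.0, 0.01)
        u = np.full(t.shape, -60.0)
        # two brief threshold excursions 0.5 ms apart -> one spike
        for t0 in (5.0, 5.5):
            sel = (t >= t0) & (t < t0 + 0.2)
            u[sel] = -20.0
        train = detect_spikes(t, u, rest=-60.0, refine=False)
        assert len(train) == 1


class TestClassifyLocking:
    def test_empty_train_is_quiescence(self):
        rep = classify_locking(make_train([]), 10.0, (0.0, 300.0))
        assert rep.mode == "quiescence"

    def test_one_spike_per_cycle_is_1_1(self):
        times = 10.0 * np.arange(30) + 6.5
        rep = classify_locking(make_train(times), 10.0, (0.0, 300.0))
        assert rep.is_locked(1, 1)
        assert rep.mean_phase == pytest.approx(65.0)
        assert rep.firing_rate == pytest.approx(100.0)

    def test_alternating_cycles_are_1_2(self):
        times = 20.0 * np.arange(15) + 5.0
        rep = classify_locking(make_train(times), 10.0, (0.0, 300.0))
        assert rep.is_locked(1, 2)

    def test_2_3_pattern_reports_two_phase_slots(self):
        # spikes in cycles 0 and 1 of every 3, at distinct phases
        times = []
        for block in range(10):
            times.append(30.0 * block + 4.0)
            times.append(30.0 * block + 10.0 + 7.0)
        rep = classify_locking(make_train(times), 10.0, (0.0, 300.0))
        assert rep.is_locked(2, 3)
        assert len(rep.slot_phases) == 2
        assert sorted(np.round(rep.slot_phases)) == [40.0, 70.0]

    def test_drifting_phase_is_irregular(self):
        rng = np.random.default_rng(0)
        times = 10.0 * np.arange(30) + rng.uniform(2.0, 8.0, 30)
        rep = classify_locking(make_train(times), 10.0, (0.0, 300.0))
        assert rep.mode == "irregular"

    def test_phase_invariant_to_whole_period_offsets(self):
        a = make_train(10.0 * np.arange(30) + 6.5)
        b = make_train(10.0 * np.arange(30) + 6.5 + 50 * 10.0)
        ra = classify_locking(a, 10.0, (0.0, 300.0))
        rb = classify_locking(b, 10.0, (500.0, 800.0))
        assert ra.mean_phase == pytest.approx(rb.mean_phase)

    def test_window_must_cover_three_cycles(self):
        with pytest.raises(ValueError):
            classify_locking(make_train([5.0]), 10.0, (0.0, 20.0))


class TestLockingRuns:
    def test_deterministic_1_1_run_has_tiny_phase_jitter(self, one_to_one_run):
        _, train, report, _ = one_to_one_run
        assert report.is_locked(1, 1)
        assert report.slot_phase_sd.max() < 0.1

    def test_no_sensilla_is_quiescent(self):
        _, rep = run_locking(volley=None, visual=-40.0)
        assert rep.mode == "quiescence"

    def test_subthreshold_fraction_is_quiescent_without_noise(self):
        _, rep = run_locking(volley=volley_from_fraction(20.0, sigma=1.0),
                             visual=-35.0)
        assert rep.mode == "quiescence"

    def test_half_active_sensilla_lock_1_2(self):
        _, rep = run_locking(volley=volley_from_fraction(50.0, sigma=1.0),
                             visual=-35.0)
        assert rep.is_locked(1, 2)

    def test_seventy_percent_locks_1_1(self, one_to_one_run):
        _, _, report, _ = one_to_one_run
        assert report.is_locked(1, 1)


class TestSweep:
    def test_mode_order_and_thresholds(self):
        df = sensilla_sweep(fractions=np.array(
            [0.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 85.0, 100.0]))
        assert df.iloc[0]["mode"] == "quiescence"
        # firing sets in between quiescence and 1:1; rate never decreases
        assert sweep_thresholds(df)["firing_threshold"] <= \
            sweep_thresholds(df)["one_to_one_threshold"]
        rates = df["firing_rate"].to_numpy()
        assert np.all(np.diff(rates) >= -1e-9)
        assert df.iloc[-1]["p"] == 1 and df.iloc[-1]["q"] == 1

    def test_phase_advances_with_more_sensilla_inside_1_1(self):
        df = sensilla_sweep(fractions=np.array([70.0, 80.0, 90.0, 100.0]))
        assert (df["p"] == 1).all() and (df["q"] == 1).all()
        assert np.all(np.diff(df["mean_phase"].to_numpy()) < 0)


class TestVisualControl:
    def test_phase_decreases_monotonically_with_uin(self):
        volley = volley_from_fraction(70.0, sigma=1.0)
        df = steady_phase_vs_uin(volley, np.arange(-40.0, -29.9, 2.0))
        assert (df["mode"] == "locked").all()
        assert np.all(np.diff(df["mean_phase"].to_numpy()) < 0)
        a, b, r2 = fit_phase_exponential(df["u_in"], df["mean_phase"])
        assert r2 >= 0.95

    def test_zero_height_step_leaves_phase_unchanged(self):
        volley = volley_from_fraction(70.0, sigma=1.0)
        res = visual_step_response(volley, u_from=-35.0, u_to=-35.0,
                                   n_settle=55, n_post=55)
        assert res.phase_shift == pytest.approx(0.0, abs=0.05)
        assert res.cycles_to_steady <= 1

    def test_depolarization_advances_spike_phase(self):
        volley = volley_from_fraction(70.0, sigma=1.0)
        res = visual_step_response(volley, u_from=-40.0, u_to=-30.0,
                                   n_settle=55, n_post=55)
        assert res.locked_throughout
        assert res.phase_shift < -0.3  # advance


class TestNoise:
    def test_noiseless_phase_sd_is_negligible(self):
        volley = volley_from_fraction(70.0, sigma=1.0)
        res = noise_phase_stability(volley, 0.0, seeds=(0,), n_cycles=60)
        assert res["phase_sd"] < 0.05

    def test_noise_widens_phase_distribution_monotonically(self):
        volley = volley_from_fraction(70.0, sigma=1.0)
        sd1 = noise_phase_stability(volley, 0.1, seeds=(0, 1), n_cycles=60)
        sd2 = noise_phase_stability(volley, 0.25, seeds=(0, 1), n_cycles=60)
        assert 0.05 < sd1["phase_sd"] < sd2["phase_sd"]

    def test_noise_triggers_intermittent_spiking_below_threshold(self):
        """Subthreshold drive plus 0.25 mV noise fires irregularly."""
        volley = volley_from_fraction(33.0, sigma=1.0)
        res = noise_phase_stability(volley, 0.25, seeds=(0, 1), n_cycles=60)
        assert 0 < res["firing_rate"] < 95.0


@pytest.fixture(scope="module")
def refractory():
    return refractory_measurement()


class TestRefractory:
    def test_absolute_below_relative_within_physiological_range(self, refractory):
        assert 0.6 < refractory.absolute < 5.0
        assert refractory.absolute < refractory.relative < 40.0

    def test_long_interval_recovers_full_amplitude(self, neuron, refractory):
        from mnb1.protocols import _pulse_run

        amp = 1.5 * refractory.pulse_amplitude / 10.0
        tr = _pulse_run(neuron, amp, [20.0, 45.0], 0.5, 0.01, 90.0)
        assert len(tr) == 2
        assert tr.amplitudes[1] == pytest.approx(tr.amplitudes[0], rel=0.02)

    def test_one_millisecond_interval_yields_single_spike(self, neuron,
                                                          refractory):
        from mnb1.protocols import _pulse_run

        tr = _pulse_run(neuron, refractory.pulse_amplitude, [20.0, 20.6],
                        0.5, 0.01, 80.0)
        assert len(tr) == 1

    def test_bisection_agrees_with_linear_scan(self, refractory):
        scan = refractory_measurement(method="scan", resolution=0.05)
        assert scan.absolute == pytest.approx(refractory.absolute, abs=0.06)


class TestGating:
    def test_scenario_i_switches_mode_with_depolarization(self):
        res = gating_scenarios("i")
        assert res["baseline"].is_locked(2, 3)
        assert res["depolarized"].is_locked(1, 1)

    def test_scenario_iii_gates_tonic_firing(self):
        res = gating_scenarios("iii")
        assert res["baseline"].mode == "quiescence"
        dep = res["depolarized"]
        assert dep.mode != "quiescence"
        assert not dep.is_locked(1, 1)
        assert 0 < dep.firing_rate < 100.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            gating_scenarios("iv")
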