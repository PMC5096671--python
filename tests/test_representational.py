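import numpy as np
import pytest

from reachdyn.representational import (
    ComplexKinematicParams,
    RepresentationalParams,
    detect_neural_movement_onset,
    latency_sweep,
    simulate_complex_kinematic,
    simulate_representational,
)
from reachdyn.task import bell_profile, kinematic_traces, make_targets


def noiseless(**kw):
    kw.setdefault("noise_sd", 0.0)
    return RepresentationalParams(**kw)


class TestVelocityModel:
    def test_gain_at_preferred_and_antipreferred_direction(self, task13):
        # b = (1 + cos(dtheta))/2: 1 at the PD, 0 opposite it
        params = noiseless(n_neurons=50, latency_sd=0.0)
        pop = simulate_representational(params, task13, seed=3)
        theta_n = pop.neuron_meta["preferred_angle"]
        peaks = pop.rates.max(axis=2)  # (N, C) noiseless peak = b
        for i in range(10):
            nearest = np.argmin(np.abs(np.angle(np.exp(1j * (task13.target_angles - theta_n[i])))))
            opposite = np.argmin(
                np.abs(np.angle(np.exp(1j * (task13.target_angles - theta_n[i] - np.pi))))
            )
            assert peaks[i, nearest] > 0.9
            assert peaks[i, opposite] < 0.1

    def test_identical_latencies_collapse_to_one_time_course(self, task13):
        params = noiseless(latency_sd=0.0)
        pop = simulate_representational(params, task13, seed=1)
        # every (neuron, condition) trace is b * shared shape
        shape = None
        for i in range(20):
            for c in range(13):
                b = pop.rates[i, c].max()
                if b < 1e-3:
                    continue
                trace = pop.rates[i, c] / b
                if shape is None:
                    shape = trace
                assert np.allclose(trace, shape, atol=1e-9)

    def test_noiseless_peak_time_and_value(self, task13):
        # brute-force argmax oracle on a dense grid
        params = noiseless(n_neurons=30)
        pop = simulate_representational(params, task13, window=(-300, 800), dt=1.0, seed=2)
        tau = pop.neuron_meta["latency_ms"]
        mu0 = params.mu0
        for i in range(10):
            c = int(np.argmax(pop.rates[i].max(axis=1)))
            b = pop.rates[i, c].max()
            t_peak = pop.time_ms[np.argmax(pop.rates[i, c])]
            assert t_peak == pytest.approx(tau[i] + mu0, abs=1.0)
            assert 0.0 <= b <= 1.0

    def test_branch_continuity_at_latency(self):
        # exp(-mu0^2 / (2 sigma^2)) == phi, so both branches meet at t = tau
        for phi in (0.1, 0.2, 0.5):
            p = RepresentationalParams(prep_fraction=phi)
            assert np.exp(-(p.mu0**2) / (2 * p.movement_sd**2)) == pytest.approx(phi, rel=1e-12)

    def test_rates_bounded_in_default_gain_mode(self, task13):
        pop = simulate_representational(noiseless(), task13, seed=5)
        assert pop.rates.min() >= 0.0 and pop.rates.max() <= 1.0 + 1e-12

    def test_latencies_recovered_from_peak_times(self, task13):
        params = noiseless(n_neurons=100)
        pop = simulate_representational(params, task13, dt=1.0, seed=8)
        tau = np.sort(pop.neuron_meta["latency_ms"])
        peak_t = pop.time_ms[pop.rates.max(axis=1).argmax(axis=1)]
        recovered = np.sort(peak_t - params.mu0)
        assert np.abs(recovered - tau).max() <= 1.0

    def test_invalid_prep_fraction_rejected(self):
        with pytest.raises(ValueError):
            RepresentationalParams(prep_fraction=0.0)
        with pytest.raises(ValueError):
            RepresentationalParams(prep_fraction=1.2)

    def test_narrow_window_rejected(self, task13):
        with pytest.raises(ValueError):
            simulate_representational(RepresentationalParams(), task13, window=(-100, 400))

    def test_seed_reproducibility(self, task13):
        a = simulate_representational(RepresentationalParams(), task13, seed=4)
        b = simulate_representational(RepresentationalParams(), task13, seed=4)
        assert np.array_equal(a.rates, b.rates)


class TestOnsetDetection:
    def test_crossing_matches_closed_form_inverse_gaussian(self, task13):
        # single shared Gaussian: onset where the grand average crosses
        # prep + 0.1 (max - prep); solve the Gaussian analytically
        params = noiseless(latency_sd=0.0)
        pop = simulate_representational(params, task13, dt=1.0, seed=1)
        onset, offset = detect_neural_movement_onset(pop)
        sig = pop.rates.mean(axis=(0, 1))
        prep, peak = sig[:5].mean(), sig.max()
        level = prep + 0.1 * (peak - prep)
        mu0, sigma = params.mu0, params.movement_sd
        # shape(t) = phi before tau, exp(-(t - mu0)^2/2 sigma^2) after (tau = 0)
        # grand average = mean(b) * shape, so crossing of shape at level/mean(b)
        scale = peak  # mean(b) since shape peaks at 1
        t_cross = mu0 - sigma * np.sqrt(-2 * np.log(level / scale))
        assert onset == pytest.approx(t_cross, abs=1.5)
        assert offset > onset

    def test_zero_threshold_gives_first_sample_above_prep(self, task13):
        pop = simulate_representational(noiseless(latency_sd=0.0), task13, seed=1)
        onset, _ = detect_neural_movement_onset(pop, threshold_fraction=0.0)
        sig = pop.rates.mean(axis=(0, 1))
        prep = sig[:5].mean()
        assert onset == pop.time_ms[np.argmax(sig > prep)]

    def test_constant_signal_raises(self):
        from reachdyn.population import PopulationActivity

        flat = PopulationActivity(
            rates=np.ones((4, 3, 50)), time_ms=np.arange(50.0) * 10, dt=10.0
        )
        with pytest.raises(ValueError):
            detect_neural_movement_onset(flat)


class TestComplexKinematic:
    def test_velocity_only_reduces_to_signed_cosine_drive(self, task13):
        kin = kinematic_traces(task13, bell_profile(400.0, 10.0), 10.0)
        params = ComplexKinematicParams(
            n_neurons=20, noise_sd=0.0, latency_sd=0.0,
            velocity_weight_mean=1.0, velocity_weight_sd=0.0,
            secondary_weight_sd=0.0, jerk_weight_sd=0.0, jerk_fraction=0.0,
        )
        pop = simulate_complex_kinematic(params, task13, kin, seed=9)
        theta_n = pop.neuron_meta["preferred_angle"]
        rms = np.sqrt(np.mean(kin.velocity**2))
        # drive = speed/rms * cos(theta_c - theta_n), plus the phi*b baseline
        i, c = 3, 5
        t_idx = pop.time_index(200.0)
        expected = (
            params.prep_fraction * 0.5 * (1 + np.cos(task13.target_angles[c] - theta_n[i]))
            + (kin.speed[np.argmin(np.abs(kin.time_ms - 200.0))] / rms)
            * np.cos(task13.target_angles[c] - theta_n[i])
        )
        assert pop.rates[i, c, t_idx] == pytest.approx(expected, rel=1e-9)

    def test_spot_check_weighted_sum(self, task13):
        kin = kinematic_traces(task13, bell_profile(400.0, 10.0), 10.0)
        params = ComplexKinematicParams(n_neurons=10, noise_sd=0.0, latency_sd=0.0)
        pop = simulate_complex_kinematic(params, task13, kin, seed=2)
        i, c = 4, 7
        th = pop.neuron_meta["preferred_angle"][i]
        t_query = 150.0
        total = params.prep_fraction * 0.5 * (1 + np.cos(task13.target_angles[c] - th))
        k_idx = np.argmin(np.abs(kin.time_ms - t_query))
        for name, key in [
            ("velocity", "w_velocity"), ("position", "w_position"),
            ("acceleration", "w_acceleration"), ("jerk", "w_jerk"),
        ]:
            trace = getattr(kin, name)
            tr = trace / np.sqrt(np.mean(trace**2))
            proj = tr[c, k_idx, 0] * np.cos(th) + tr[c, k_idx, 1] * np.sin(th)
            total += pop.neuron_meta[key][i] * proj
        assert pop.rates[i, c, pop.time_index(t_query)] == pytest.approx(total, rel=1e-9)

    def test_missing_trace_raises(self, task13):
        kin = kinematic_traces(task13, bell_profile(400.0, 10.0), 10.0)
        kin.jerk = None
        with pytest.raises(ValueError):
            simulate_complex_kinematic(ComplexKinematicParams(n_neurons=5), task13, kin, seed=0)


class TestLatencySweep:
    def test_grid_shape_and_latency_effect(self):
        grid = latency_sweep([0.0, 72.0], [56.0], task=make_targets(8),
                             reps=2, seed=0, n_neurons=60)
        assert grid.shape == (2, 1)
        # rotational structure rises when latency SD exceeds movement SD
        assert grid[1, 0] > grid[0, 0]

    def test_high_latency_beats_low_latency_majority(self, task13):
        # Monte-Carlo ordering oracle at the headline movement SD
        wins = 0
        reps = 6
        for s in range(reps):
            g = latency_sweep([0.0, 100.0], [56.0], task=task13, reps=1,
                              seed=s, n_neurons=100)
            if g[1, 0] > g[0, 0]:
                wins += 1
        assert wins > reps // 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            latency_sweep([], [56.0])
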