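import numpy as np
import pytest

from reachdyn.population import PopulationActivity
from reachdyn.task import make_targets
from reachdyn.tuning import (
    demo_latency_pcs,
    fit_preferred_directions,
    population_vector,
    preferred_direction_timecourse,
    tuning_stability,
    velocity_regression,
)

from helpers import cosine_population, eq12_population


class TestPreferredDirections:
    def test_pure_sine_tuning_recovered(self):
        task = make_targets(13)
        rates = np.sin(task.target_angles)[None, :, None] * np.ones((1, 13, 10))
        pop = PopulationActivity(
            rates=rates, time_ms=np.arange(10) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        fit = fit_preferred_directions(pop, window=(0.0, 90.0))
        assert fit.coeffs[0] == pytest.approx([0.0, 1.0, 0.0], abs=1e-10)
        assert fit.modulation_depth[0] == pytest.approx(1.0)
        assert np.degrees(fit.preferred_angle[0]) == pytest.approx(90.0)

    def test_random_coefficients_recovered_exactly(self, rng):
        task = make_targets(13)
        b = rng.normal(size=(20, 3))
        X = np.column_stack(
            [np.ones(13), np.sin(task.target_angles), np.cos(task.target_angles)]
        )
        rates = (X @ b.T).T[:, :, None] * np.ones((20, 13, 5))
        pop = PopulationActivity(
            rates=rates, time_ms=np.arange(5) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        fit = fit_preferred_directions(pop, window=(0.0, 40.0))
        assert np.allclose(fit.coeffs, b, atol=1e-10)

    def test_constant_rate_flagged_untuned(self):
        task = make_targets(8)
        pop = PopulationActivity(
            rates=np.ones((3, 8, 6)), time_ms=np.arange(6) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        fit = fit_preferred_directions(pop, window=(0.0, 50.0))
        assert fit.untuned.all()
        assert np.all(fit.modulation_depth < 1e-10)

    def test_too_few_conditions_rejected(self, rng):
        task = make_targets(2)
        pop = PopulationActivity(
            rates=rng.normal(size=(3, 2, 6)), time_ms=np.arange(6) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        with pytest.raises(ValueError):
            fit_preferred_directions(pop)


class TestPopulationVector:
    def test_uniform_cosine_population_is_exact(self, rng):
        task = make_targets(13)
        pop, _ = cosine_population(400, task, rng, uniform_pds=True)
        fit = fit_preferred_directions(pop, window=(0.0, 300.0))
        pv = population_vector(pop, fit, window=(0.0, 300.0))
        err = np.degrees(np.abs(np.angle(np.exp(1j * (pv.predicted_angle - pv.actual_angle)))))
        assert err.max() < 1.0

    def test_error_decreases_with_population_size(self, rng):
        task = make_targets(13)
        errs = []
        for n in (50, 500):
            pop, _ = cosine_population(n, task, rng, gain=1.0)
            # jitter the gains so finite-size error is visible
            pop.rates += 0.05 * rng.normal(size=pop.rates.shape)
            fit = fit_preferred_directions(pop, window=(0.0, 300.0))
            pv = population_vector(pop, fit, window=(0.0, 300.0))
            err = np.degrees(
                np.abs(np.angle(np.exp(1j * (pv.predicted_angle - pv.actual_angle))))
            )
            errs.append(err.mean())
        assert errs[1] < errs[0]

    def test_linearity_under_rate_scaling(self, rng):
        task = make_targets(13)
        pop, _ = cosine_population(50, task, rng)
        fit = fit_preferred_directions(pop, window=(0.0, 300.0))
        pv1 = population_vector(pop, fit, window=(0.0, 300.0))
        doubled = PopulationActivity(
            rates=2 * pop.rates, time_ms=pop.time_ms, dt=pop.dt,
            events=dict(pop.events), condition_meta=dict(pop.condition_meta),
        )
        fit2 = fit_preferred_directions(doubled, window=(0.0, 300.0))
        pv2 = population_vector(doubled, fit2, window=(0.0, 300.0))
        assert np.allclose(
            np.linalg.norm(pv2.population_vector, axis=-1),
            2 * np.linalg.norm(pv1.population_vector, axis=-1),
            rtol=1e-9,
        )

    def test_all_untuned_rejected(self):
        task = make_targets(8)
        pop = PopulationActivity(
            rates=np.ones((3, 8, 6)), time_ms=np.arange(6) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        fit = fit_preferred_directions(pop, window=(0.0, 50.0))
        with pytest.raises(ValueError):
            population_vector(pop, fit, window=(0.0, 50.0))


class TestVelocityRegression:
    def test_parameter_recovery(self, rng):
        pop, speed, speed_t = eq12_population()
        fit = velocity_regression(pop, speed, speed_t, window=(0.0, 300.0))
        assert fit.lag_ms[0] == pytest.approx(40.0, abs=10.0)
        assert fit.adjusted_r2[0] > 0.99
        a = fit.coeffs[0]
        assert a[0] == pytest.approx(0.3, rel=0.05)
        assert a[1] == pytest.approx(1.2, rel=0.05)
        # a3/a4 identified up to the product with a5; check the direction
        assert np.arctan2(a[2], a[3]) == pytest.approx(np.arctan2(0.8, -0.5), abs=0.05)

    def test_constant_neuron_zero_fit(self):
        task = make_targets(8)
        t = np.arange(-200.0, 510.0, 10.0)
        pop = PopulationActivity(
            rates=np.full((1, 8, t.size), 0.7), time_ms=t, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        speed_t = np.arange(0.0, 310.0, 10.0)
        speed = np.sin(np.pi * speed_t / 300.0) ** 2
        fit = velocity_regression(pop, speed, speed_t, window=(0.0, 300.0))
        assert fit.adjusted_r2[0] == 0.0
        assert np.allclose(fit.coeffs[0, 1:4], 0.0)


class TestTuningStability:
    def test_zero_delta_perfect_correlation(self, rng):
        task = make_targets(13)
        pop, _ = cosine_population(30, task, rng)
        pop.events["neural_movement_onset"] = 150.0
        deltas, mean_corr, corr = tuning_stability(pop, max_delta=100.0)
        assert deltas[0] == 0.0
        assert mean_corr[0] == pytest.approx(1.0, abs=1e-9)

    def test_static_tuning_stays_correlated(self, rng):
        # shape changes over time but condition order never does
        task = make_targets(13)
        pop, _ = cosine_population(30, task, rng)
        pop.events["neural_movement_onset"] = 50.0
        _, mean_corr, _ = tuning_stability(pop, max_delta=150.0)
        assert np.all(mean_corr > 0.999)

    def test_too_few_conditions_rejected(self, rng):
        task = make_targets(2)
        pop = PopulationActivity(
            rates=rng.normal(size=(3, 2, 30)), time_ms=np.arange(30) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        with pytest.raises(ValueError):
            tuning_stability(pop)

    def test_rnn_tuning_decays_with_elapsed_time(self, rnn_pop):
        deltas, mean_corr, _ = tuning_stability(rnn_pop, max_delta=200.0)
        drops = np.diff(mean_corr[2:])
        assert np.sum(drops > 0.0) <= 1  # non-increasing, one violation allowed
        assert mean_corr[-1] < mean_corr[0]


class TestPreferredDirectionTimecourse:
    def test_ideal_cosine_constant_pd(self, rng):
        task = make_targets(13)
        pop, theta_n = cosine_population(10, task, rng)
        pd_map = preferred_direction_timecourse(pop)
        inner = pd_map[:, 1:-1]  # envelope is ~0 at the edges (untuned there)
        for i in range(10):
            vals = inner[i][inner[i] >= 0]
            assert len(np.unique(vals)) == 1

    def test_flat_rates_marked_untuned(self):
        task = make_targets(8)
        pop = PopulationActivity(
            rates=np.ones((2, 8, 5)), time_ms=np.arange(5) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        assert np.all(preferred_direction_timecourse(pop) == -1)

    def test_matches_brute_force_scan(self, rng):
        task = make_targets(6)
        pop = PopulationActivity(
            rates=rng.normal(size=(4, 6, 20)), time_ms=np.arange(20) * 10.0, dt=10.0,
            events={"go_cue": 0.0},
            condition_meta={"target_angles": task.target_angles},
        )
        pd_map = preferred_direction_timecourse(pop)
        for i in range(4):
            for t in range(20):
                assert pd_map[i, t] == int(np.argmax(pop.rates[i, :, t]))


class TestLatencyPcsDemo:
    def test_zero_shift_is_rank_one(self):
        _, _, _, ratio = demo_latency_pcs(n_signals=6, shift_sd=0.0, seed=0)
        assert ratio[0] > 0.999

    def test_zero_crossings_increase_with_pc_index(self):
        _, _, pcs, _ = demo_latency_pcs(n_signals=40, shift_sd=60.0, seed=1)
        counts = []
        for k in range(4):
            sig = pcs[k] - pcs[k].mean()
            counts.append(int(np.sum(np.abs(np.diff(np.sign(sig))) > 1)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_horseshoe_curvature_single_signed(self):
        # discrete-curvature sign oracle on the PC1-PC2 plane trace
        _, _, pcs, _ = demo_latency_pcs(n_signals=40, shift_sd=60.0, seed=1)
        x, y = pcs[0], pcs[1]
        cross = np.diff(x)[:-1] * np.diff(y)[1:] - np.diff(y)[:-1] * np.diff(x)[1:]
        dominant = np.sign(np.median(cross))
        assert np.mean(np.sign(cross) == dominant) > 0.9

    def test_too_few_signals_rejected(self):
        with pytest.raises(ValueError):
            demo_latency_pcs(n_signals=2)
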