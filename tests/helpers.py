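"""Shared synthetic-population builders for the test suite."""

import numpy as np

from reachdyn.population import PopulationActivity
from reachdyn.task import make_targets


def cosine_population(n_neurons, task, rng, gain=1.0, baseline=0.5, n_t=31,
                      uniform_pds=False):
    """Ideal cosine-tuned neurons with a shared temporal envelope.

    ``uniform_pds=True`` places preferred directions on an exact uniform grid
    (the limit in which population-vector decoding is exact by symmetry).
    """
    t = np.arange(n_t) * 10.0
    envelope = np.sin(np.pi * t / t[-1])
    if uniform_pds:
        theta_n = 2 * np.pi * np.arange(n_neurons) / n_neurons
    else:
        theta_n = rng.uniform(0, 2 * np.pi, n_neurons)
    dtheta = task.target_angles[None, :] - theta_n[:, None]
    rates = baseline + gain * np.cos(dtheta)[:, :, None] * envelope[None, None, :]
    pop = PopulationActivity(
        rates=rates, time_ms=t, dt=10.0, events={"go_cue": 0.0},
        condition_meta={"target_angles": task.target_angles},
        neuron_meta={"preferred_angle": theta_n},
    )
    return pop, theta_n


def eq12_population(tau_true=40.0, a=(0.3, 1.2, 0.8, -0.5, 0.6)):
    """One neuron generated exactly from the lagged velocity-tuning model."""
    task = make_targets(13)
    t = np.arange(-200.0, 510.0, 10.0)
    speed_t = np.arange(0.0, 310.0, 10.0)
    speed = np.sin(np.pi * speed_t / 300.0) ** 2
    a1, a2, a3, a4, a5 = a
    rates = np.zeros((1, 13, t.size))
    for c, th in enumerate(task.target_angles):
        drive = a1 + np.interp(t, speed_t, speed, left=0, right=0) * (
            a2 + a3 * np.sin(th) + a4 * np.cos(th)
        ) + a5 * (a3 * np.sin(th) + a4 * np.cos(th))
        # R(t - tau) = drive(t)  =>  R(s) = drive(s + tau)
        rates[0, c] = np.interp(t + tau_true, t, drive)
    pop = PopulationActivity(
        rates=rates, time_ms=t, dt=10.0, events={"go_cue": 0.0},
        condition_meta={"target_angles": task.target_angles},
    )
    return pop, speed, speed_t
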