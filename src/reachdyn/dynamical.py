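"""Two-oscillator dynamical-system population simulator.

Muscle-like activity during reaching is modeled as a sum of two complex
oscillators with fixed frequencies (2.8 Hz and 0.3 Hz) whose phase, amplitude
and constant offset vary by condition:

    F_{c,k}(t) = a_{c,k} * exp(i (2 pi f_k t - theta_{c,k}))

Each simulated neuron mixes the two condition-level oscillations and the
offset with its own five scalar weights (real/imaginary parts of two complex
coefficients plus an offset coefficient, all standard normal):

    r_{n,c}(t) = Re(w_{n,1} F_{c,1}(t) + w_{n,2} F_{c,2}(t)) + s_n o_c + eps

Preparatory activity is built by holding the first movement sample (noise
included) constant for 100 ms before the go cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationActivity
from .task import ReachTask

__all__ = [
    "DynamicalParams",
    "sample_condition_params",
    "oscillator",
    "simulate_dynamical",
]


@dataclass
class DynamicalParams:
    n_neurons: int = 200
    frequencies: tuple = (2.8, 0.3)           # Hz
    phase_range: tuple = (0.0, np.pi / 2)     # theta_{c,k}
    amplitude_range: tuple = (-2.5, -1.5)     # a_{c,k}
    offset_range: tuple = (-5.5, -4.5)        # o_c
    noise_sd: float = 0.01                    # matched to the velocity-tuning model
    prep_extension: float = 100.0             # ms of held preparatory activity

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("oscillator frequencies must be positive")


def sample_condition_params(task: ReachTask, params: DynamicalParams, seed: int = 0):
    """Draw per-condition phases, amplitudes and offsets from their ranges."""
    rng = np.random.default_rng(seed)
    c, k = task.n_conditions, len(params.frequencies)
    phases = rng.uniform(*params.phase_range, size=(c, k))
    amplitudes = rng.uniform(*sorted(params.amplitude_range), size=(c, k))
    offsets = rng.uniform(*sorted(params.offset_range), size=c)
    return {"phases": phases, "amplitudes": amplitudes, "offsets": offsets}


def oscillator(a: float, f_hz: float, theta: float, time_ms: np.ndarray) -> np.ndarray:
    """Complex oscillation a * exp(i (2 pi f t - theta)), t in seconds."""
    t = np.asarray(time_ms, dtype=float) / 1000.0
    return a * np.exp(1j * (2 * np.pi * f_hz * t - theta))


def simulate_dynamical(
    task: ReachTask,
    params: DynamicalParams = None,
    duration: float = 300.0,
    dt: float = 10.0,
    seed: int = 0,
) -> PopulationActivity:
    """Simulate the oscillator-mixture population.

    The movement epoch runs from the go cue (t = 0) to ``duration``; the
    preparatory epoch extends the first movement sample backwards by
    ``prep_extension`` ms. Neural movement onset is the go cue.
    """
    params = params or DynamicalParams()
    rng = np.random.default_rng(seed)
    cond = sample_condition_params(task, params, seed=int(rng.integers(2**31)))
    n, c = params.n_neurons, task.n_conditions
    move_t = np.arange(0.0, duration + dt / 2, dt)

    # (C, K, T) complex oscillations
    F = np.stack(
        [
            np.stack(
                [
                    oscillator(cond["amplitudes"][ci, ki], params.frequencies[ki],
                               cond["phases"][ci, ki], move_t)
                    for ki in range(len(params.frequencies))
                ]
            )
            for ci in range(c)
        ]
    )

    w = rng.standard_normal((n, len(params.frequencies), 2))
    w_complex = w[..., 0] + 1j * w[..., 1]      # (N, K)
    s = rng.standard_normal(n)

    move = np.real(np.einsum("nk,ckt->nct", w_complex, F)) + s[:, None, None] * cond["offsets"][None, :, None]
    if params.noise_sd > 0:
        move = move + rng.normal(0.0, params.noise_sd, size=move.shape)

    n_prep = int(round(params.prep_extension / dt))
    prep = np.repeat(move[:, :, :1], n_prep, axis=2)  # held first sample, noise included
    rates = np.concatenate([prep, move], axis=2)
    time_ms = np.arange(-n_prep, move_t.size) * dt

    return PopulationActivity(
        rates=rates,
        time_ms=time_ms,
        dt=dt,
        events={"go_cue": 0.0, "neural_movement_onset": 0.0, "movement_end": float(duration)},
        neuron_meta={"w_re_1": w[:, 0, 0], "w_im_1": w[:, 0, 1],
                     "w_re_2": w[:, 1, 0], "w_im_2": w[:, 1, 1], "s": s},
        condition_meta={"target_angles": task.target_angles,
                        "offsets": cond["offsets"],
                        "phases_k1": cond["phases"][:, 0],
                        "phases_k2": cond["phases"][:, 1],
                        "amplitudes_k1": cond["amplitudes"][:, 0],
                        "amplitudes_k2": cond["amplitudes"][:, 1]},
        generator="dynamical",
        seed=seed,
        params={"frequencies": list(params.frequencies), "noise_sd": params.noise_sd},
    )
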