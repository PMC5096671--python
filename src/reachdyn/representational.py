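"""Cosine-tuned (representational) population simulators.

Two generators live here:

* the velocity-tuning model: each neuron is cosine-tuned to reach direction,
  with a Gaussian movement-activity bump of SD ``movement_sd`` whose timing is
  offset per neuron by a normally distributed neuron-kinematic latency, and a
  flat preparatory level that is a fixed fraction ``prep_fraction`` of the
  movement peak;
* the complex-kinematic variant: the same latency structure, but each
  neuron's drive is a weighted sum of the directional projections of
  velocity, position, acceleration and (for a subset of neurons) jerk.

The noiseless velocity-model rate of neuron *n* in condition *c* is

    f(t) = phi * b            for t <  tau_n
    f(t) = b * exp(-(t - tau_n - mu0)^2 / (2 sigma^2))   for t >= tau_n

with b the directional gain, mu0 = sigma * sqrt(-2 ln phi) so that the two
branches meet continuously at t = tau_n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .population import PopulationActivity
from .task import KinematicSet, ReachTask

__all__ = [
    "RepresentationalParams",
    "ComplexKinematicParams",
    "simulate_representational",
    "simulate_complex_kinematic",
    "detect_neural_movement_onset",
    "latency_sweep",
]

GAIN_MODES = ("offset_cosine", "signed_cosine", "random_gain")


@dataclass
class RepresentationalParams:
    """Parameters of the velocity-tuning population.

    ``latency_sd`` and ``movement_sd`` are the two knobs of the latency sweep;
    ``prep_fraction`` (phi) sets preparatory activity to one fifth of the
    movement peak by default.
    """

    n_neurons: int = 200
    latency_sd: float = 72.0      # ms, SD of tau_n
    latency_mean: float = 0.0     # ms, mean of tau_n relative to the go cue
    movement_sd: float = 56.0     # ms, sigma
    prep_fraction: float = 0.2    # phi
    noise_sd: float = 0.01
    gain_mode: str = "offset_cosine"
    random_gain_range: tuple = (0.5, 1.5)
    noise_per_sample: bool = True  # i.i.d. per sample vs per (neuron, condition)

    def __post_init__(self) -> None:
        if not 0 < self.prep_fraction < 1:
            raise ValueError("prep_fraction must lie strictly between 0 and 1")
        if self.latency_sd < 0 or self.movement_sd <= 0:
            raise ValueError("latency_sd must be >= 0 and movement_sd > 0")
        if self.gain_mode not in GAIN_MODES:
            raise ValueError(f"gain_mode must be one of {GAIN_MODES}")

    @property
    def mu0(self) -> float:
        """Offset placing the movement peak so that the bump starts at phi."""
        return self.movement_sd * np.sqrt(-2.0 * np.log(self.prep_fraction))


@dataclass
class ComplexKinematicParams(RepresentationalParams):
    """Velocity model extended with position/acceleration/jerk sensitivity.

    Per-neuron weights multiply the directional projection of each kinematic
    trace onto the neuron's preferred direction; traces are pre-scaled to unit
    RMS so the weights are comparable across parameters. Velocity dominates;
    position and acceleration carry weights at half the velocity scale (the
    neurons are genuinely multi-parameter, not velocity-only), and a quarter
    of the neurons also carry a jerk weight.
    """

    velocity_weight_mean: float = 1.0
    velocity_weight_sd: float = 0.2
    secondary_weight_sd: float = 0.5   # position & acceleration
    jerk_weight_sd: float = 0.5
    jerk_fraction: float = 0.25


def _gains(params: RepresentationalParams, task: ReachTask, rng: np.random.Generator):
    """Directional gain b_{n,c} and the neurons' preferred angles."""
    theta_n = rng.uniform(0.0, 2 * np.pi, size=params.n_neurons)
    dtheta = task.target_angles[None, :] - theta_n[:, None]  # (N, C)
    if params.gain_mode == "signed_cosine":
        b = np.cos(dtheta)
    else:
        b = 0.5 * (1.0 + np.cos(dtheta))
        if params.gain_mode == "random_gain":
            lo, hi = params.random_gain_range
            b = b * rng.uniform(lo, hi, size=params.n_neurons)[:, None]
    return b, theta_n


def _add_noise(rates, params: RepresentationalParams, rng: np.random.Generator):
    if params.noise_sd <= 0:
        return rates
    if params.noise_per_sample:
        return rates + rng.normal(0.0, params.noise_sd, size=rates.shape)
    per_trace = rng.normal(0.0, params.noise_sd, size=rates.shape[:2])
    return rates + per_trace[:, :, None]


def simulate_representational(
    params: RepresentationalParams,
    task: ReachTask,
    window: tuple = (-300.0, 800.0),
    dt: float = 10.0,
    seed: int = 0,
) -> PopulationActivity:
    """Simulate the cosine-tuned population on ``window`` (ms around go cue)."""
    if window[0] > -200.0 or window[1] < 600.0:
        raise ValueError("window must span at least [-200, +600] ms around the go cue")
    rng = np.random.default_rng(seed)
    b, theta_n = _gains(params, task, rng)
    tau = rng.normal(params.latency_mean, params.latency_sd, size=params.n_neurons)
    time_ms = np.arange(window[0], window[1] + dt / 2, dt)
    mu0 = params.mu0
    t_rel = time_ms[None, :] - tau[:, None]  # (N, T)
    bump = np.exp(-0.5 * ((t_rel - mu0) / params.movement_sd) ** 2)
    shape = np.where(t_rel < 0.0, params.prep_fraction, bump)  # (N, T)
    rates = b[:, :, None] * shape[:, None, :]
    rates = _add_noise(rates, params, rng)
    return PopulationActivity(
        rates=rates,
        time_ms=time_ms,
        dt=dt,
        events={"go_cue": 0.0},
        neuron_meta={"latency_ms": tau, "preferred_angle": theta_n},
        condition_meta={"target_angles": task.target_angles},
        generator="representational",
        seed=seed,
        params={
            "latency_sd": params.latency_sd,
            "movement_sd": params.movement_sd,
            "prep_fraction": params.prep_fraction,
            "noise_sd": params.noise_sd,
            "gain_mode": params.gain_mode,
        },
    )


def simulate_complex_kinematic(
    params: ComplexKinematicParams,
    task: ReachTask,
    kin: KinematicSet,
    window: tuple = (-300.0, 800.0),
    seed: int = 0,
) -> PopulationActivity:
    """Simulate the complex-kinematic population.

    Each neuron's movement drive is the latency-shifted weighted sum of the
    directional projections of the kinematic traces onto its preferred
    direction; the preparatory level is the same phi-scaled cosine gain as in
    the velocity model, so the model reduces to (a signed-gain version of) it
    when all non-velocity weights vanish.
    """
    for name in ("velocity", "position", "acceleration", "jerk"):
        if getattr(kin, name, None) is None:
            raise ValueError(f"kinematic set is missing the {name} trace")
    dt = kin.dt
    rng = np.random.default_rng(seed)
    b, theta_n = _gains(params, task, rng)
    tau = rng.normal(params.latency_mean, params.latency_sd, size=params.n_neurons)
    n = params.n_neurons

    w_vel = rng.normal(params.velocity_weight_mean, params.velocity_weight_sd, size=n)
    w_pos = rng.normal(0.0, params.secondary_weight_sd, size=n)
    w_acc = rng.normal(0.0, params.secondary_weight_sd, size=n)
    w_jerk = rng.normal(0.0, params.jerk_weight_sd, size=n)
    w_jerk[rng.random(n) >= params.jerk_fraction] = 0.0

    time_ms = np.arange(window[0], window[1] + dt / 2, dt)
    T = time_ms.size
    rates = np.empty((n, task.n_conditions, T))

    # directional projection of each (C, Tk, 2) trace onto each neuron's PD,
    # pre-scaled to unit RMS so weights are comparable across parameters
    cos_n, sin_n = np.cos(theta_n), np.sin(theta_n)
    projections = {}
    for name, weights in (
        ("velocity", w_vel),
        ("position", w_pos),
        ("acceleration", w_acc),
        ("jerk", w_jerk),
    ):
        trace = getattr(kin, name)  # (C, Tk, 2)
        rms = np.sqrt(np.mean(trace**2))
        if rms > 0:
            trace = trace / rms
        # (N, C, Tk)
        projections[name] = (
            weights[:, None, None]
            * (cos_n[:, None, None] * trace[None, :, :, 0] + sin_n[:, None, None] * trace[None, :, :, 1])
        )

    drive = sum(projections.values())  # (N, C, Tk)
    t_kin = kin.time_ms

    # per-neuron latency shift: movement drive occupies t in [tau_n, tau_n + dur];
    # outside the kinematic window traces are edge-padded (the hand rests at the
    # center before the reach and at the target after it)
    for i in range(n):
        t_rel = time_ms - tau[i]
        idx = np.clip(np.round((t_rel - t_kin[0]) / dt).astype(int), 0, t_kin.size - 1)
        rates[i] = params.prep_fraction * b[i][:, None] + drive[i][:, idx]

    rates = _add_noise(rates, params, rng)
    return PopulationActivity(
        rates=rates,
        time_ms=time_ms,
        dt=dt,
        events={"go_cue": 0.0},
        neuron_meta={
            "latency_ms": tau,
            "preferred_angle": theta_n,
            "w_velocity": w_vel,
            "w_position": w_pos,
            "w_acceleration": w_acc,
            "w_jerk": w_jerk,
        },
        condition_meta={"target_angles": task.target_angles},
        generator="complex_kinematic",
        seed=seed,
        params={"latency_sd": params.latency_sd, "noise_sd": params.noise_sd},
    )


def detect_neural_movement_onset(
    pop: PopulationActivity,
    threshold_fraction: float = 0.1,
    baseline_samples: int = 5,
    min_range: float = 1e-6,
) -> tuple:
    """Threshold crossing of the grand-average rate.

    The preparatory level is the mean of the grand average over the first
    ``baseline_samples`` samples; onset is the first time the grand average
    exceeds ``prep + threshold_fraction * (max - prep)`` and offset the last
    time it does. Both are stored into ``pop.events``.
    """
    signal = pop.rates.mean(axis=(0, 1))
    prep = signal[:baseline_samples].mean()
    peak = signal.max()
    if peak - prep <= min_range:
        raise ValueError("no onset detectable: signal range below the noise floor")
    level = prep + threshold_fraction * (peak - prep)
    above = signal > level
    if not above.any():
        raise ValueError("no onset detectable: grand average never crosses threshold")
    onset = float(pop.time_ms[np.argmax(above)])
    offset = float(pop.time_ms[len(above) - 1 - np.argmax(above[::-1])])
    pop.events["neural_movement_onset"] = onset
    pop.events["movement_end"] = offset
    return onset, offset


def latency_sweep(
    latency_sds,
    movement_sds,
    task: ReachTask = None,
    reps: int = 5,
    seed: int = 0,
    n_neurons: int = 200,
    jpca_config=None,
) -> np.ndarray:
    """Mean rotational goodness-of-fit over a (latency SD, movement SD) grid.

    For each cell the cosine-tuned population is simulated ``reps`` times with
    fresh seeds, run through jPCA over all planes, and the mean RGR returned.
    Output shape is (len(latency_sds), len(movement_sds)).
    """
    from .jpca import JpcaConfig, jpca_analyze
    from .task import make_targets

    latency_sds = np.atleast_1d(np.asarray(latency_sds, dtype=float))
    movement_sds = np.atleast_1d(np.asarray(movement_sds, dtype=float))
    if latency_sds.size == 0 or movement_sds.size == 0:
        raise ValueError("latency_sds and movement_sds must be non-empty")
    if task is None:
        task = make_targets(13)
    cfg = jpca_config or JpcaConfig()
    root = np.random.default_rng(seed)
    grid = np.zeros((latency_sds.size, movement_sds.size))
    for i, lsd in enumerate(latency_sds):
        for j, msd in enumerate(movement_sds):
            vals = []
            for _ in range(reps):
                s = int(root.integers(2**31))
                params = RepresentationalParams(
                    n_neurons=n_neurons, latency_sd=lsd, movement_sd=msd
                )
                pop = simulate_representational(params, task, seed=s)
                try:
                    detect_neural_movement_onset(pop)
                    res = jpca_analyze(pop, cfg)
                    vals.append(res.rgr_all)
                except ValueError as err:  # degenerate cell (e.g. flat signal)
                    warnings.warn(f"sweep cell ({lsd}, {msd}) skipped a rep: {err}")
            grid[i, j] = np.mean(vals) if vals else np.nan
    return grid
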