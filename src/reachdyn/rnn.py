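"""Continuous-rate recurrent network trained to produce reach velocities.

The network obeys the standard rate equation

    tau dx_i/dt = -x_i + sum_k J_ik r_k(t) + sum_k B_ik u_k(t)
    r = 0 for x < 0, tanh(x) for x >= 0          (rectified tanh)
    z = W r                                       (2-D velocity readout)

integrated with the Euler method (dt = 10 ms, tau = 50 ms). Inputs are a
hold signal (1 until the go cue, 0 after) and the target direction as
(sin theta, cos theta). Targets are zero during the delay and a bell-shaped
x/y velocity profile starting ``reaction_time`` ms after the go cue.

Training minimizes the normalized squared output error plus three
regularizers (mean squared rate, squared sum of input/output weights, and a
trajectory-complexity surrogate: the mean squared discrete state velocity).
Gradients are computed by backpropagation through time in closed form and
fed to L-BFGS; the gradient is validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .population import PopulationActivity
from .task import ReachTask, bell_profile

__all__ = [
    "RnnModel",
    "TrainingConfig",
    "TrialSet",
    "init_network",
    "make_trials",
    "simulate_rnn",
    "normalized_error",
    "train",
    "export_population",
]


@dataclass
class RnnModel:
    J: np.ndarray              # (N, N) recurrent weights
    B: np.ndarray              # (N, I) input weights
    W: np.ndarray              # (2, N) readout weights
    tau: float = 50.0          # ms
    dt: float = 10.0           # ms
    g: float = 1.5

    @property
    def N(self) -> int:
        return self.J.shape[0]

    @property
    def I(self) -> int:
        return self.B.shape[1]


@dataclass
class TrainingConfig:
    delays: tuple = (600.0, 800.0, 1000.0)   # ms, go-cue times
    reaction_time: float = 100.0             # ms between go cue and movement
    movement_duration: float = 300.0         # ms
    tail: float = 100.0                      # ms of enforced stillness after movement
    reg_rate: float = 1e-2
    reg_weights: float = 2e-5
    reg_complexity: float = 5e-5
    target_error: float = 1e-3               # normalized error; 0.1%
    max_iter: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reg_rate", "reg_weights", "reg_complexity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrialSet:
    """Inputs and velocity targets, one batch per delay.

    ``inputs[delay]`` has shape (T, 3, C): hold signal, sin(theta),
    cos(theta); ``targets[delay]`` has shape (T, 2, C).
    """

    inputs: dict
    targets: dict
    dt: float
    task: ReachTask
    go_cue: dict = field(default_factory=dict)   # delay -> go-cue time (ms)


def rectified_tanh(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.tanh(x), 0.0)


def _rectified_tanh_deriv(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 - np.tanh(x) ** 2, 0.0)


def init_network(
    n_units: int = 200,
    n_inputs: int = 3,
    g: float = 1.5,
    tau: float = 50.0,
    dt: float = 10.0,
    seed: int = 0,
    j_scale: str = "conventional",
) -> RnnModel:
    """Random network: J ~ N(0, sd), B ~ N(0, 1/N), W = 0.

    ``j_scale='conventional'`` (default) uses the standard chaotic-network
    scaling sd = g/sqrt(N); ``'printed'`` uses sd = g/N. The conventional
    scaling reaches the training criterion far faster; see docs/methods.md.
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    sd = g / n_units if j_scale == "printed" else g / np.sqrt(n_units)
    J = rng.normal(0.0, sd, size=(n_units, n_units))
    B = rng.normal(0.0, 1.0 / n_units, size=(n_units, n_inputs))
    W = np.zeros((2, n_units))
    return RnnModel(J=J, B=B, W=W, tau=tau, dt=dt, g=g)


def make_trials(task: ReachTask, cfg: TrainingConfig, dt: float = 10.0) -> TrialSet:
    """Build the input/target batch for every delay and condition."""
    c = task.n_conditions
    sin_t, cos_t = np.sin(task.target_angles), np.cos(task.target_angles)
    bell = bell_profile(cfg.movement_duration, dt, radius=task.reach_radius)
    inputs, targets, go_cue = {}, {}, {}
    for delay in cfg.delays:
        total = delay + cfg.reaction_time + cfg.movement_duration + cfg.tail
        steps = int(round(total / dt))
        t = np.arange(steps) * dt
        u = np.zeros((steps, 3, c))
        u[:, 0, :] = (t < delay).astype(float)[:, None]   # hold until go cue
        u[:, 1, :] = sin_t[None, :]
        u[:, 2, :] = cos_t[None, :]
        v = np.zeros((steps, 2, c))
        m0 = int(round((delay + cfg.reaction_time) / dt))
        v[m0 : m0 + bell.size, 0, :] = bell[:, None] * cos_t[None, :]
        v[m0 : m0 + bell.size, 1, :] = bell[:, None] * sin_t[None, :]
        inputs[delay], targets[delay], go_cue[delay] = u, v, float(delay)
    return TrialSet(inputs=inputs, targets=targets, dt=dt, task=task, go_cue=go_cue)


def simulate_rnn(model: RnnModel, u: np.ndarray, x0: np.ndarray = None):
    """Euler-integrate the network for one input batch.

    ``u`` is (T, I, C). Returns states x (T+1, N, C) (x[0] is the initial
    state), rates r (T+1, N, C) and outputs z (T+1, 2, C).
    """
    steps, _, c = u.shape
    n = model.N
    alpha = model.dt / model.tau
    x = np.empty((steps + 1, n, c))
    x[0] = 0.0 if x0 is None else x0
    for t in range(steps):
        r_t = rectified_tanh(x[t])
        x[t + 1] = x[t] + alpha * (-x[t] + model.J @ r_t + model.B @ u[t])
        if not np.all(np.isfinite(x[t + 1])):
            raise FloatingPointError("network state diverged during simulation")
    r = rectified_tanh(x)
    z = np.einsum("on,tnc->toc", model.W, r)
    return x, r, z


def normalized_error(z: np.ndarray, v: np.ndarray) -> float:
    """Sum of squared output errors divided by total target variance."""
    if z.shape != v.shape:
        raise ValueError("output and target shapes must match")
    sst = np.sum((v - v.mean()) ** 2)
    if sst <= 0:
        raise ValueError("target signal has zero variance")
    return float(np.sum((z - v) ** 2) / sst)


def _loss_and_grad(params, shapes, model: RnnModel, trials: TrialSet, cfg: TrainingConfig):
    """Full loss and analytic gradient via backprop through time."""
    n, i_in = shapes
    J = params[: n * n].reshape(n, n)
    B = params[n * n : n * n + n * i_in].reshape(n, i_in)
    W = params[n * n + n * i_in :].reshape(2, n)
    alpha = model.dt / model.tau
    dt_ms = model.dt

    sst = sum(np.sum((v - v.mean()) ** 2) for v in trials.targets.values())
    n_rate = sum(u.shape[0] * n * u.shape[2] for u in trials.inputs.values())

    loss = 0.0
    gJ = np.zeros_like(J)
    gB = np.zeros_like(B)
    gW = np.zeros_like(W)
    mdl = RnnModel(J=J, B=B, W=W, tau=model.tau, dt=model.dt, g=model.g)

    for delay, u in trials.inputs.items():
        v = trials.targets[delay]
        steps = u.shape[0]
        x, r, z = simulate_rnn(mdl, u)
        # output error on steps 1..steps (state after each input step)
        e = z[1:] - v                                    # (T, 2, C)
        loss += np.sum(e**2) / sst
        loss += cfg.reg_rate * np.sum(r**2) / n_rate
        dx = np.diff(x, axis=0) / dt_ms                  # (T, N, C)
        loss += cfg.reg_complexity * np.sum(dx**2) / n_rate

        # backward pass
        delta = np.zeros((n, u.shape[2]))                # dL/dx_{t+1} accumulator
        k_c = 2.0 * cfg.reg_complexity / (n_rate * dt_ms**2)
        for t in range(steps, 0, -1):
            g_r = (
                W.T @ (2.0 * e[t - 1] / sst)
                + 2.0 * cfg.reg_rate * r[t] / n_rate
            )
            if t < steps:
                g_r += J.T @ (alpha * delta)
            # complexity penalty: d/dx_t of sum ||x_{s+1}-x_s||^2 / dt_s^2
            c_t = k_c * (2.0 * x[t] - x[t + 1] - x[t - 1]) if t < steps else k_c * (x[t] - x[t - 1])
            delta_t = _rectified_tanh_deriv(x[t]) * g_r + c_t
            if t < steps:
                delta_t += (1.0 - alpha) * delta
            gW += (2.0 * e[t - 1] / sst) @ r[t].T
            gJ += (alpha * delta_t) @ rectified_tanh(x[t - 1]).T
            gB += (alpha * delta_t) @ u[t - 1].T
            delta = delta_t
        # complexity gradient w.r.t. x_0 is dropped: x_0 is a constant (zeros)

    loss += cfg.reg_weights * (np.sum(B**2) + np.sum(W**2))
    gB += 2.0 * cfg.reg_weights * B
    gW += 2.0 * cfg.reg_weights * W
    grad = np.concatenate([gJ.ravel(), gB.ravel(), gW.ravel()])
    return loss, grad


def _total_normalized_error(model: RnnModel, trials: TrialSet) -> float:
    sse, sst = 0.0, 0.0
    for delay, u in trials.inputs.items():
        v = trials.targets[delay]
        _, _, z = simulate_rnn(model, u)
        sse += np.sum((z[1:] - v) ** 2)
        sst += np.sum((v - v.mean()) ** 2)
    return sse / sst


class _Converged(Exception):
    pass


def train(model: RnnModel, trials: TrialSet, cfg: TrainingConfig):
    """Train J, B, W jointly with L-BFGS on the analytic BPTT gradient.

    Stops at ``cfg.target_error`` normalized error or after ``cfg.max_iter``
    iterations. Returns ``(trained_model, info)`` with the error trace and
    whether the 0.1% criterion was reached.
    """
    n, i_in = model.N, model.I
    x0 = np.concatenate([model.J.ravel(), model.B.ravel(), model.W.ravel()])
    error_trace = []
    best = {"params": x0.copy(), "err": np.inf}

    def unpack(p):
        return RnnModel(
            J=p[: n * n].reshape(n, n),
            B=p[n * n : n * n + n * i_in].reshape(n, i_in),
            W=p[n * n + n * i_in :].reshape(2, n),
            tau=model.tau, dt=model.dt, g=model.g,
        )

    def fun(p):
        return _loss_and_grad(p, (n, i_in), model, trials, cfg)

    def callback(p):
        err = _total_normalized_error(unpack(p), trials)
        error_trace.append(err)
        if err < best["err"]:
            best["params"], best["err"] = p.copy(), err
        if err < cfg.target_error:
            raise _Converged

    try:
        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": cfg.max_iter, "maxcor": 20, "ftol": 1e-14, "gtol": 1e-12},
        )
        final = res.x
    except _Converged:
        final = best["params"]
    if not np.all(np.isfinite(final)):
        raise FloatingPointError("training diverged: non-finite parameters")
    trained = unpack(final)
    err = _total_normalized_error(trained, trials)
    if best["err"] < err:
        trained, err = unpack(best["params"]), best["err"]
    info = {
        "normalized_error": float(err),
        "reached_0p1_percent": bool(err < 1e-3),
        "error_trace": np.asarray(error_trace),
        "n_iterations": len(error_trace),
    }
    return trained, info


def export_population(model: RnnModel, trials: TrialSet, delay: float = 800.0) -> PopulationActivity:
    """Unit rates for one delay set as a :class:`PopulationActivity`.

    The time axis is relative to the go cue; the movement epoch used by the
    rotational analyses is go cue to go + 300 ms.
    """
    if delay not in trials.inputs:
        raise KeyError(f"delay {delay} not in trial set")
    u = trials.inputs[delay]
    _, r, _ = simulate_rnn(model, u)
    rates = np.transpose(r[1:], (1, 2, 0))   # (N, C, T)
    time_ms = np.arange(1, u.shape[0] + 1) * trials.dt - delay
    return PopulationActivity(
        rates=rates,
        time_ms=time_ms,
        dt=trials.dt,
        events={"go_cue": 0.0, "neural_movement_onset": 0.0, "movement_end": 300.0},
        condition_meta={"target_angles": trials.task.target_angles},
        generator="rnn",
        params={"delay": float(delay)},
    )
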