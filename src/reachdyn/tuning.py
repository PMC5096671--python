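"""Representational read-outs and single-unit tuning characterization.

Classical analyses applied to any :class:`PopulationActivity`:

* preferred-direction fitting by sinusoidal regression of per-condition mean
  movement rates, R_c = b1 + b2 sin(theta_c) + b3 cos(theta_c);
* the population vector P(t) = sum_i (R_i(t) - b_{i,1}) C_i, its integral
  (predicted trajectory) and per-condition predicted direction;
* lagged velocity regression of single-unit activity on speed-scaled cosine
  tuning plus a preparatory-tuning term, searching the neuron-kinematic lag
  on a grid;
* tuning-stability correlation over time and preferred-direction maps;
* the time-shifted-signal PCA demonstration (Fourier-like components and the
  "horseshoe" plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .population import PopulationActivity
from .task import KinematicSet

__all__ = [
    "TuningFit",
    "PopulationVectorResult",
    "VelocityRegressionFit",
    "fit_preferred_directions",
    "population_vector",
    "velocity_regression",
    "tuning_stability",
    "preferred_direction_timecourse",
    "demo_latency_pcs",
]


@dataclass
class TuningFit:
    coeffs: np.ndarray            # (N, 3): b1, b2, b3
    modulation_depth: np.ndarray  # (N,) k = sqrt(b2^2 + b3^2)
    preferred_vector: np.ndarray  # (N, 2) unit vectors [b2/k, b3/k]; NaN if untuned
    untuned: np.ndarray           # (N,) bool

    @property
    def preferred_angle(self) -> np.ndarray:
        """Preferred direction in radians (atan2 of the [sin, cos] weights)."""
        return np.arctan2(self.preferred_vector[:, 0], self.preferred_vector[:, 1])


@dataclass
class PopulationVectorResult:
    time_ms: np.ndarray
    contributions: np.ndarray     # (N, C, T, 2)
    population_vector: np.ndarray  # (C, T, 2)
    trajectory: np.ndarray        # (C, T, 2) running integral of P
    predicted_angle: np.ndarray   # (C,) angle of sum_t P(t)
    actual_angle: np.ndarray      # (C,)


@dataclass
class VelocityRegressionFit:
    coeffs: np.ndarray            # (N, 5): a1..a5
    lag_ms: np.ndarray            # (N,)
    adjusted_r2: np.ndarray       # (N,)
    r2: np.ndarray                # (N,)


def _movement_window(pop: PopulationActivity, window):
    if window is None:
        go = pop.events.get("go_cue", 0.0)
        window = (go, go + 300.0)
    return pop.window_slice(*window)


def fit_preferred_directions(pop: PopulationActivity, window=None) -> TuningFit:
    """Sinusoidal regression of mean movement-period rate on target angle."""
    if pop.n_conditions < 3:
        raise ValueError("need at least 3 conditions to fit 3 coefficients")
    angles = np.asarray(pop.condition_meta["target_angles"], dtype=float)
    sl = _movement_window(pop, window)
    R = pop.rates[:, :, sl].mean(axis=2)     # (N, C)
    X = np.column_stack([np.ones_like(angles), np.sin(angles), np.cos(angles)])
    coeffs, *_ = np.linalg.lstsq(X, R.T, rcond=None)
    coeffs = coeffs.T                         # (N, 3)
    k = np.sqrt(coeffs[:, 1] ** 2 + coeffs[:, 2] ** 2)
    untuned = k <= 1e-10 * np.maximum(1.0, np.abs(coeffs[:, 0]))
    pref = np.full((pop.n_neurons, 2), np.nan)
    pref[~untuned] = coeffs[~untuned, 1:] / k[~untuned, None]
    return TuningFit(coeffs=coeffs, modulation_depth=k, preferred_vector=pref, untuned=untuned)


def population_vector(pop: PopulationActivity, fit: TuningFit, window=None) -> PopulationVectorResult:
    """Population-vector decoding over the movement period."""
    if fit.untuned.all():
        raise ValueError("all neurons untuned; population vector undefined")
    sl = _movement_window(pop, window)
    rates = pop.rates[:, :, sl]               # (N, C, T)
    tuned = ~fit.untuned
    resid = rates - fit.coeffs[:, 0][:, None, None]
    contrib = np.zeros(rates.shape + (2,))
    contrib[tuned] = resid[tuned, :, :, None] * fit.preferred_vector[tuned][:, None, None, :]
    P = contrib.sum(axis=0)                   # (C, T, 2)
    traj = np.cumsum(P, axis=1) * pop.dt
    overall = P.sum(axis=1)                   # (C, 2); sum over time
    predicted = np.arctan2(overall[:, 0], overall[:, 1])
    # C_i = [b2/k, b3/k] pairs with (sin, cos): component 0 is the sin (y-ish)
    # axis, so angle = atan2(P_sin, P_cos).
    actual = np.asarray(pop.condition_meta["target_angles"], dtype=float)
    return PopulationVectorResult(
        time_ms=pop.time_ms[sl],
        contributions=contrib,
        population_vector=P,
        trajectory=traj,
        predicted_angle=predicted,
        actual_angle=actual,
    )


def velocity_regression(
    pop: PopulationActivity,
    speed: np.ndarray,
    speed_time_ms: np.ndarray,
    lag_grid=None,
    a5_grid=None,
    window=None,
) -> VelocityRegressionFit:
    """Lagged velocity-tuning regression per neuron.

    Model: R(t - tau) = a1 + |V(t)| (a2 + a3 sin th + a4 cos th)
                           + a5 (a3 sin th + a4 cos th).
    For each lag tau on the grid the model is nonlinear only through a5, so
    a5 is profiled on a grid (with a golden-section refinement) and the
    remaining coefficients solved by linear least squares; the lag with the
    best adjusted R-squared is kept (ties to the smallest |tau|). Adjusted
    R-squared counts 6 fitted quantities (a1..a5 and the searched lag).
    """
    if lag_grid is None:
        lag_grid = np.arange(-200.0, 201.0, 10.0)
    if a5_grid is None:
        a5_grid = np.linspace(-3.0, 3.0, 25)
    angles = np.asarray(pop.condition_meta["target_angles"], dtype=float)
    sl = _movement_window(pop, window)
    move_t = pop.time_ms[sl]
    speed_at = np.interp(move_t, speed_time_ms, speed, left=0.0, right=0.0)  # (T,)
    c, t_len = pop.n_conditions, move_t.size
    n_obs = c * t_len
    sin_t, cos_t = np.sin(angles), np.cos(angles)

    # design pieces, flattened over (C, T)
    sp = np.broadcast_to(speed_at, (c, t_len)).ravel()
    sn = np.repeat(sin_t, t_len)
    cs = np.repeat(cos_t, t_len)

    n_param = 6
    coeffs = np.zeros((pop.n_neurons, 5))
    lags = np.zeros(pop.n_neurons)
    r2s = np.zeros(pop.n_neurons)
    adj = np.zeros(pop.n_neurons)

    for i in range(pop.n_neurons):
        best = (-np.inf, None, None, None)   # adjusted r2, lag, a, a5
        any_admissible = False
        for lag in lag_grid:
            shifted_t = move_t - lag
            if shifted_t[0] < pop.time_ms[0] or shifted_t[-1] > pop.time_ms[-1]:
                continue
            any_admissible = True
            y = np.stack(
                [np.interp(shifted_t, pop.time_ms, pop.rates[i, ci]) for ci in range(c)]
            ).ravel()
            sst = np.sum((y - y.mean()) ** 2)
            if sst <= y.size * (1e-9 * max(1.0, np.abs(y).max())) ** 2:
                continue  # (numerically) constant trace

            def sse_of(a5):
                X = np.column_stack([np.ones(n_obs), sp, (sp + a5) * sn, (sp + a5) * cs])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                return np.sum((y - X @ beta) ** 2), beta

            sses = [sse_of(a5)[0] for a5 in a5_grid]
            k0 = int(np.argmin(sses))
            lo = a5_grid[max(k0 - 1, 0)]
            hi = a5_grid[min(k0 + 1, len(a5_grid) - 1)]
            from scipy.optimize import minimize_scalar
            opt = minimize_scalar(lambda a5: sse_of(a5)[0], bounds=(lo, hi), method="bounded")
            a5 = float(opt.x)
            sse, beta = sse_of(a5)
            r2 = 1.0 - sse / sst
            a = 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_param)
            if a > best[0] + 1e-12 or (
                abs(a - best[0]) <= 1e-12
                and best[1] is not None
                and abs(lag) < abs(best[1])
            ):
                best = (a, lag, beta, a5)
        if best[1] is None:
            if not any_admissible:
                raise ValueError(f"no admissible lag for neuron {i}; extend the data window")
            # constant-rate neuron: no tuning, zero fit quality
            mean_rate = float(pop.rates[i, :, sl].mean())
            coeffs[i] = [mean_rate, 0.0, 0.0, 0.0, 0.0]
            lags[i], adj[i], r2s[i] = 0.0, 0.0, 0.0
            continue
        a_adj, lag, beta, a5 = best
        coeffs[i] = [beta[0], beta[1], beta[2], beta[3], a5]
        lags[i] = lag
        adj[i] = a_adj
        r2s[i] = 1.0 - (1.0 - a_adj) * (n_obs - n_param) / (n_obs - 1)
    return VelocityRegressionFit(coeffs=coeffs, lag_ms=lags, adjusted_r2=adj, r2=r2s)


def tuning_stability(
    pop: PopulationActivity,
    reference: float = None,
    step: float = 10.0,
    max_delta: float = 200.0,
    method: str = "pearson",
):
    """Correlation of the per-condition tuning vector over elapsed time.

    For each neuron, the length-C vector of rates at the reference time is
    correlated with the vector at reference + delta. Returns
    ``(deltas_ms, mean_corr, corr_matrix)`` where corr_matrix is
    (neurons, deltas) with NaN for neurons whose tuning vector has zero
    variance at either time.
    """
    if pop.n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    if reference is None:
        reference = pop.events.get("neural_movement_onset", pop.events.get("go_cue", 0.0))
    deltas = np.arange(0.0, max_delta + step / 2, step)
    i_ref = pop.time_index(reference)
    ref_vec = pop.rates[:, :, i_ref]          # (N, C)
    corr = np.full((pop.n_neurons, deltas.size), np.nan)
    for j, d in enumerate(deltas):
        i_t = pop.time_index(reference + d)
        vec = pop.rates[:, :, i_t]
        for i in range(pop.n_neurons):
            a, b = ref_vec[i], vec[i]
            if a.std() == 0 or b.std() == 0:
                continue
            if method == "pearson":
                corr[i, j] = stats.pearsonr(a, b)[0]
            else:
                corr[i, j] = stats.spearmanr(a, b)[0]
    return deltas, np.nanmean(corr, axis=0), corr


def preferred_direction_timecourse(pop: PopulationActivity, untuned_epsilon: float = 1e-4):
    """Condition of maximal rate per neuron and time point.

    Returns an (N, T) integer map of preferred conditions, -1 where the
    max-min rate difference is below ``untuned_epsilon`` (untuned).
    """
    pd_map = np.argmax(pop.rates, axis=1)     # (N, T)
    spread = pop.rates.max(axis=1) - pop.rates.min(axis=1)
    pd_map = np.where(spread < untuned_epsilon, -1, pd_map)
    return pd_map


def demo_latency_pcs(
    n_signals: int = 6,
    shift_sd: float = 50.0,
    duration: float = 600.0,
    signal_sd: float = 56.0,
    dt: float = 10.0,
    seed: int = 0,
    n_components: int = 4,
):
    """PCA of identically shaped, randomly time-shifted Gaussian signals.

    Demonstrates how latency offsets alone produce Fourier-like components of
    increasing frequency and a curved ("horseshoe") trace in the PC1-PC2
    plane. Returns ``(time_ms, signals, pcs, explained_ratio)`` where pcs is
    (n_components, T).
    """
    if n_signals < 3:
        raise ValueError("need at least 3 signals")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    shifts = rng.normal(0.0, shift_sd, size=n_signals)
    center = duration / 2
    signals = np.exp(-0.5 * ((t[None, :] - center - shifts[:, None]) / signal_sd) ** 2)
    X = signals - signals.mean(axis=1, keepdims=True)
    from sklearn.decomposition import PCA

    n_components = min(n_components, n_signals, t.size)
    pca = PCA(n_components=n_components)
    pca.fit(X)
    pcs = pca.components_                      # (k, T) time courses
    return t, signals, pcs, pca.explained_variance_ratio_
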