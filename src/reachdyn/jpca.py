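"""Rotational-dynamics analysis (jPCA).

Population activity in an analysis window is normalized per neuron, reduced
to the top ``d`` principal components, and two linear dynamical laws are fit
to the reduced state X and its temporal derivative X_dot (adjacent-sample
differences within each condition):

    X_dot = M X           (unconstrained least squares)
    X_dot = M_skew X      (least squares over exactly skew-symmetric matrices)

Planes of purely rotational flow are the eigenplanes of M_skew, ordered by
rotation frequency and oriented anticlockwise. Three summary metrics follow:

* variance fraction per plane (relative to total normalized data variance),
* the rotational goodness-of-fit ratio RGR = R2_skew / R2_unconstrained,
* circularity: mean over states of the unsigned angle between x and x_dot
  divided by pi/2 (1 for purely circular flow, 0 for purely radial flow).

The skew-symmetric fit is solved in closed form on the d(d-1)/2 free
parameters; a brute-force optimizer reproduces it in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .population import PopulationActivity

__all__ = [
    "JpcaConfig",
    "JpcaResult",
    "preprocess",
    "fit_dynamics",
    "fit_skew_dynamics",
    "extract_planes",
    "rotation_metrics",
    "jpca_analyze",
    "resolve_window",
]


@dataclass
class JpcaConfig:
    d: int = 6                      # retained PCs (even)
    dt: float = 10.0                # ms, sampling step of the analysis
    window: tuple | None = None     # (t0, t1) ms; None -> from events
    soften: float = 0.05            # normalization constant added to the range
    normalize: bool = True
    subtract_cc_mean: bool = True   # cross-condition (per-timepoint) mean removal

    def __post_init__(self) -> None:
        if self.d < 2 or self.d % 2 != 0:
            raise ValueError("d must be an even integer >= 2")


@dataclass
class JpcaResult:
    x_red: np.ndarray               # (d, C, Tw) reduced state
    x_dot: np.ndarray               # (d, C, Tw-1) temporal derivative (1/ms)
    M: np.ndarray                   # unconstrained dynamics matrix (d, d)
    M_skew: np.ndarray              # skew-symmetric dynamics matrix (d, d)
    planes: list                    # orthonormal (d, 2) bases, frequency-ordered
    plane_frequencies_hz: np.ndarray
    variance_fractions: np.ndarray  # per plane, relative to total data variance
    rgr_plane1: float
    rgr_all: float                  # full d-dimensional fit ("all jPCA planes")
    circularity: float
    pc_variance_ratio: np.ndarray   # per retained PC
    time_ms: np.ndarray             # window time axis
    pc_timecourses: np.ndarray = field(default=None)  # (d, C, Tw)

    @property
    def rgr_planes123(self) -> float:
        """RGR over the first three planes (= the full fit when d = 6)."""
        return self.rgr_all if len(self.planes) <= 3 else self._rgr_first_k(3)

    def plane_projection(self, k: int) -> np.ndarray:
        """(2, C, Tw) trajectory of all conditions in plane ``k``."""
        return np.einsum("dj,dct->jct", self.planes[k], self.x_red)

    def _rgr_first_k(self, k: int) -> float:
        basis = np.concatenate(self.planes[:k], axis=1)
        return _rgr_in_subspace(self.x_red, self.x_dot, self.M, self.M_skew, basis)

    def metrics(self) -> dict:
        return {
            "variance_per_plane": self.variance_fractions.tolist(),
            "rgr_plane1": self.rgr_plane1,
            "rgr_planes123": self.rgr_planes123,
            "rgr_all": self.rgr_all,
            "circularity": self.circularity,
        }


def resolve_window(pop: PopulationActivity, cfg: JpcaConfig) -> tuple:
    """Analysis window: explicit config, detected onset/offset, or go+300."""
    if cfg.window is not None:
        return tuple(cfg.window)
    ev = pop.events
    if "neural_movement_onset" in ev and "movement_end" in ev:
        return (ev["neural_movement_onset"], ev["movement_end"])
    if "go_cue" in ev:
        return (ev["go_cue"], ev["go_cue"] + 300.0)
    raise ValueError("no analysis window: set cfg.window or population events")


def preprocess(pop: PopulationActivity, cfg: JpcaConfig):
    """Normalize, center and PCA-reduce the population.

    Returns ``(x_red, x_dot, pc_variance_ratio, total_variance, time_ms, loadings)``
    where ``x_red`` is (d, C, Tw) and ``x_dot`` the within-condition
    adjacent-sample difference divided by dt (so never spanning condition
    boundaries).
    """
    if pop.n_neurons < cfg.d:
        raise ValueError(f"need at least d={cfg.d} neurons, got {pop.n_neurons}")
    if pop.n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    t0, t1 = resolve_window(pop, cfg)
    sl = pop.window_slice(t0, t1)
    data = pop.rates[:, :, sl].astype(float).copy()  # (N, C, Tw)
    time_ms = pop.time_ms[sl]
    if time_ms.size < 3:
        raise ValueError("analysis window must contain at least 3 time samples")

    if cfg.normalize:
        rng_ = data.max(axis=(1, 2)) - data.min(axis=(1, 2))
        data /= (rng_ + cfg.soften)[:, None, None]
    if cfg.subtract_cc_mean:
        data -= data.mean(axis=1, keepdims=True)

    n, c, tw = data.shape
    flat = data.reshape(n, c * tw)
    flat = flat - flat.mean(axis=1, keepdims=True)

    pca = PCA(n_components=cfg.d)
    scores = pca.fit_transform(flat.T)            # (C*Tw, d)
    x_red = scores.T.reshape(cfg.d, c, tw)
    total_variance = float(pca.explained_variance_[0] / pca.explained_variance_ratio_[0])
    x_dot = np.diff(x_red, axis=2) / cfg.dt       # (d, C, Tw-1)
    return x_red, x_dot, pca.explained_variance_ratio_, total_variance, time_ms, pca.components_


def _flatten_for_fit(x_red: np.ndarray, x_dot: np.ndarray):
    """Align states with their derivatives: drop the last sample per condition."""
    d, c, tw = x_red.shape
    X = x_red[:, :, :-1].reshape(d, c * (tw - 1))
    Xd = x_dot.reshape(d, c * (tw - 1))
    return X, Xd


def _skew_basis(d: int):
    basis = []
    for a in range(d):
        for b_ in range(a + 1, d):
            E = np.zeros((d, d))
            E[a, b_], E[b_, a] = 1.0, -1.0
            basis.append(E)
    return basis


def fit_skew_dynamics(X: np.ndarray, Xd: np.ndarray) -> np.ndarray:
    """Closed-form least-squares skew-symmetric fit of Xd ~ S X.

    Solves the normal equations on the d(d-1)/2 free parameters of S.
    """
    d = X.shape[0]
    basis = _skew_basis(d)
    m = len(basis)
    G = X @ X.T
    H = X @ Xd.T  # (d, d); <E X, Xd> = tr(E H)
    A = np.empty((m, m))
    b = np.empty(m)
    for i, Ei in enumerate(basis):
        EiG = Ei @ G
        b[i] = np.sum(Ei * H.T)
        for j, Ej in enumerate(basis):
            A[i, j] = np.sum(EiG * Ej)
    coef = np.linalg.solve(A, b)
    S = np.zeros((d, d))
    for ci, Ei in zip(coef, basis):
        S += ci * Ei
    return S


def fit_dynamics(x_red: np.ndarray, x_dot: np.ndarray):
    """Unconstrained and skew-symmetric dynamics matrices (M, M_skew)."""
    X, Xd = _flatten_for_fit(x_red, x_dot)
    d = X.shape[0]
    if X.shape[1] < d + 1:
        raise ValueError("need at least d+1 samples to fit the dynamics")
    G = X @ X.T
    if np.linalg.matrix_rank(G) < d:
        raise np.linalg.LinAlgError("reduced state is rank deficient; cannot fit dynamics")
    M = np.linalg.solve(G, X @ Xd.T).T
    M_skew = fit_skew_dynamics(X, Xd)
    # enforce exact antisymmetry against floating-point drift
    M_skew = 0.5 * (M_skew - M_skew.T)
    return M, M_skew


def extract_planes(M_skew: np.ndarray, x_red: np.ndarray = None, dt: float = 10.0):
    """Eigenplanes of M_skew, ordered by |rotation frequency| descending.

    Each plane is an orthonormal (d, 2) basis built from the real and
    imaginary parts of one eigenvector of a conjugate pair. When trajectories
    are supplied, each basis is oriented so the mean signed angular velocity
    of the projected trajectories is positive (anticlockwise net rotation).
    Returns ``(planes, frequencies_hz)``.
    """
    d = M_skew.shape[0]
    if d % 2 != 0:
        raise ValueError("skew matrix must have even dimension")
    eigvals, eigvecs = np.linalg.eig(M_skew)
    pos = np.where(eigvals.imag > 1e-14)[0]
    order = pos[np.argsort(-np.abs(eigvals.imag[pos]), kind="stable")]
    planes, freqs = [], []
    used = len(order)
    for idx in order:
        v = eigvecs[:, idx]
        basis = np.stack([v.real, v.imag], axis=1)
        q, _ = np.linalg.qr(basis)
        planes.append(q)
        freqs.append(np.abs(eigvals[idx].imag) / (2 * np.pi) * 1000.0)  # 1/ms -> Hz
    if used < d // 2:
        warnings.warn("M_skew has (near-)zero eigenvalues: plane(s) without rotation retained")
        # pad with an orthonormal completion of the null space
        have = np.concatenate(planes, axis=1) if planes else np.zeros((d, 0))
        q_full, _ = np.linalg.qr(np.eye(d) - have @ have.T)
        rest = q_full[:, : d - have.shape[1]]
        for k in range(0, rest.shape[1] - 1, 2):
            planes.append(rest[:, k : k + 2])
            freqs.append(0.0)
    if x_red is not None:
        for k, basis in enumerate(planes):
            proj = np.einsum("dj,dct->jct", basis, x_red)  # (2, C, Tw)
            x, y = proj[0], proj[1]
            # signed angular velocity via the cross product of successive states
            cross = x[:, :-1] * np.diff(y, axis=1) - y[:, :-1] * np.diff(x, axis=1)
            if cross.mean() < 0:
                planes[k] = basis * np.array([1.0, -1.0])
    return planes, np.asarray(freqs)


def _r2(X, Xd, A, basis=None):
    resid = Xd - A @ X
    if basis is not None:
        resid = basis.T @ resid
        Xd = basis.T @ Xd
    sst = np.sum(Xd**2)
    if sst <= 0:
        raise ValueError("zero total variation in the derivative; RGR undefined")
    return 1.0 - np.sum(resid**2) / sst


def _rgr_in_subspace(x_red, x_dot, M, M_skew, basis):
    X, Xd = _flatten_for_fit(x_red, x_dot)
    r2_m = _r2(X, Xd, M, basis)
    if abs(r2_m) < 1e-12:
        raise ValueError("unconstrained fit explains ~zero variance; RGR undefined")
    return _r2(X, Xd, M_skew, basis) / r2_m


def rotation_metrics(x_red, x_dot, M, M_skew, planes, total_variance=None):
    """Variance per plane, RGR (plane 1 and full fit) and circularity."""
    X, Xd = _flatten_for_fit(x_red, x_dot)
    d = X.shape[0]
    n_samples = x_red.shape[1] * x_red.shape[2]
    if total_variance is None:
        total_variance = np.sum(x_red**2) / (n_samples - 1)
    var_frac = np.array(
        [
            np.sum(np.einsum("dj,dct->jct", basis, x_red) ** 2) / (n_samples - 1) / total_variance
            for basis in planes
        ]
    )
    rgr_all = _rgr_in_subspace(x_red, x_dot, M, M_skew, np.eye(d))
    rgr_plane1 = _rgr_in_subspace(x_red, x_dot, M, M_skew, planes[0])

    # circularity in the top plane: unsigned angle between x and x_dot over pi/2
    p = planes[0]
    px, pdx = p.T @ X, p.T @ Xd
    nx = np.linalg.norm(px, axis=0)
    ndx = np.linalg.norm(pdx, axis=0)
    ok = (nx > 1e-12) & (ndx > 1e-12)
    cosang = np.abs(np.sum(px[:, ok] * pdx[:, ok], axis=0)) / (nx[ok] * ndx[ok])
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    circularity = float(np.clip(np.mean(ang) / (np.pi / 2), 0.0, 1.0))
    return var_frac, rgr_plane1, rgr_all, circularity


def jpca_analyze(pop: PopulationActivity, cfg: JpcaConfig = None) -> JpcaResult:
    """Run the full pipeline on a population and return a :class:`JpcaResult`."""
    cfg = cfg or JpcaConfig()
    x_red, x_dot, ratio, total_var, time_ms, _ = preprocess(pop, cfg)
    M, M_skew = fit_dynamics(x_red, x_dot)
    planes, freqs = extract_planes(M_skew, x_red, cfg.dt)
    var_frac, rgr1, rgr_all, circ = rotation_metrics(
        x_red, x_dot, M, M_skew, planes, total_variance=total_var
    )
    return JpcaResult(
        x_red=x_red,
        x_dot=x_dot,
        M=M,
        M_skew=M_skew,
        planes=planes,
        plane_frequencies_hz=freqs,
        variance_fractions=var_frac,
        rgr_plane1=rgr1,
        rgr_all=rgr_all,
        circularity=circ,
        pc_variance_ratio=ratio,
        time_ms=time_ms,
        pc_timecourses=x_red,
    )
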