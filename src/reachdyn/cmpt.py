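"""Covariance-matched permutation test (CMPT) for rotational structure.

The test asks whether rotational dynamics depend uniquely on the
neuron-to-condition assignment. Each repetition:

1. randomly reassigns whole condition time-courses within each neuron
   (no values altered, nothing exchanged between neurons);
2. greedily swaps random condition pairs within random neurons, accepting a
   swap only if it strictly increases the similarity between the permuted and
   observed neuron-by-neuron covariance matrices, until similarity reaches a
   threshold (95% by default);
3. re-runs jPCA on the matched data and records the rotational
   goodness-of-fit ratio (RGR).

The p-value is the fraction of repetitions whose null RGR reaches the
observed one; the effect size is the observed RGR's z-score against the null
distribution. An "unshuffle" control correlates each repetition's null RGR
with how much of the original condition assignment it retained (after a
conservative row sorting), to verify that matching does not simply undo the
shuffle.

Covariance similarity is 1 - SSD(C_obs, C_perm) / TSS(C_obs), with TSS the
summed squared deviation of the observed covariance entries from their mean.
The greedy matcher updates the covariance and the SSD incrementally (a
within-neuron swap changes a single row/column); the update is verified
against full recomputation in the test suite. The inner loop is JIT-compiled
with numba.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .jpca import JpcaConfig, jpca_analyze, resolve_window
from .population import PopulationActivity

__all__ = [
    "CmptConfig",
    "CmptResult",
    "permute_assignments",
    "covariance_similarity",
    "match_covariance",
    "run_cmpt",
    "unshuffle_check",
    "subset_grid",
]


@dataclass
class CmptConfig:
    n_reps: int = 100
    similarity_threshold: float = 0.95
    max_swaps: int | None = None      # default 200 * neurons * conditions
    statistic: str = "all"            # RGR plane set: "all" | "planes123" | "plane1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class CmptResult:
    observed_rgr: float
    null_rgrs: np.ndarray
    p_value: float
    effect_size: float
    similarity_achieved: np.ndarray
    assignments: np.ndarray            # (reps, conditions, neurons)
    n_failed: int
    swap_stats: np.ndarray             # (reps, 2): proposals, accepted
    unshuffle_r: float | None = None
    unshuffle_p: float | None = None
    retained_fractions: np.ndarray = field(default=None)

    @property
    def p_upper_bound(self) -> float:
        """Reported bound when no null value reached the observed statistic."""
        return 1.0 / len(self.null_rgrs)


def _statistic(result, which: str) -> float:
    return {
        "all": result.rgr_all,
        "planes123": result.rgr_planes123,
        "plane1": result.rgr_plane1,
    }[which]


def permute_assignments(pop: PopulationActivity, seed=0):
    """Randomly reassign condition time-courses within each neuron.

    Returns the permuted population and the assignment matrix A of shape
    (conditions, neurons): A[c, n] is the original condition whose trace now
    occupies slot c for neuron n.
    """
    if pop.n_conditions < 2:
        raise ValueError("cannot permute with fewer than 2 conditions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, c, _ = pop.rates.shape
    assignment = np.empty((c, n), dtype=np.int64)
    permuted = np.empty_like(pop.rates)
    for i in range(n):
        perm = rng.permutation(c)
        permuted[i] = pop.rates[i, perm]
        assignment[:, i] = perm
    out = PopulationActivity(
        rates=permuted,
        time_ms=pop.time_ms.copy(),
        dt=pop.dt,
        events=dict(pop.events),
        condition_meta=dict(pop.condition_meta),
        generator=pop.generator + "+permuted",
    )
    return out, assignment


def _window_matrix(pop: PopulationActivity, window) -> np.ndarray:
    sl = pop.window_slice(*window)
    return pop.rates[:, :, sl].reshape(pop.n_neurons, -1)


def covariance_similarity(obs: PopulationActivity, perm: PopulationActivity, window) -> float:
    """Similarity of neuron-by-neuron covariance matrices over ``window``."""
    if obs.rates.shape != perm.rates.shape:
        raise ValueError("populations must have identical shapes")
    c_obs = np.cov(_window_matrix(obs, window))
    c_perm = np.cov(_window_matrix(perm, window))
    tss = np.sum((c_obs - c_obs.mean()) ** 2)
    if tss <= 0:
        raise ValueError("observed covariance has zero variance; similarity undefined")
    return min(1.0, 1.0 - np.sum((c_obs - c_perm) ** 2) / tss)


@njit(cache=False)
def _greedy_match(A, Cmat, Cobs, tss, threshold, max_swaps, assignment, seed):
    """Greedy within-neuron condition-pair swapping toward the observed covariance.

    ``A`` is the row-centered permuted data, shape (N, C, T), modified in
    place together with ``Cmat`` (current covariance) and ``assignment``.
    Returns (proposals, accepted, final_ssd).
    """
    np.random.seed(seed)
    n, c, t = A.shape
    ct1 = c * t - 1
    ssd = 0.0
    for i in range(n):
        for j in range(n):
            diff = Cmat[i, j] - Cobs[i, j]
            ssd += diff * diff
    target_ssd = (1.0 - threshold) * tss
    proposals = 0
    accepted = 0
    dc = np.empty(n)
    while ssd > target_ssd and proposals < max_swaps:
        proposals += 1
        i = np.random.randint(n)
        c1 = np.random.randint(c)
        c2 = np.random.randint(c)
        if c1 == c2:
            continue
        delta_ssd = 0.0
        for j in range(n):
            if j == i:
                dc[j] = 0.0
                continue
            acc = 0.0
            for s in range(t):
                acc += (A[i, c2, s] - A[i, c1, s]) * (A[j, c1, s] - A[j, c2, s])
            dcj = acc / ct1
            dc[j] = dcj
            old = Cmat[i, j] - Cobs[i, j]
            new = old + dcj
            delta_ssd += 2.0 * (new * new - old * old)
        if delta_ssd < 0.0:
            accepted += 1
            ssd += delta_ssd
            for s in range(t):
                tmp = A[i, c1, s]
                A[i, c1, s] = A[i, c2, s]
                A[i, c2, s] = tmp
            for j in range(n):
                Cmat[i, j] += dc[j]
                Cmat[j, i] = Cmat[i, j]
            tmpa = assignment[c1, i]
            assignment[c1, i] = assignment[c2, i]
            assignment[c2, i] = tmpa
    return proposals, accepted, ssd


def match_covariance(
    perm: PopulationActivity,
    obs: PopulationActivity,
    cfg: CmptConfig,
    window,
    assignment=None,
    seed=0,
):
    """Greedy covariance matching of a permuted population to the observed one.

    Swaps are proposed uniformly over (neuron, condition pair); a proposal is
    accepted only if covariance similarity strictly increases. Stops at the
    similarity threshold or after ``max_swaps`` proposals. Returns
    ``(assignment, similarity, info)``: the updated slot-to-original-condition
    assignment (apply it to the observed population to obtain the matched
    data), the final similarity, and swap statistics.
    """
    n, c, _ = perm.rates.shape
    if assignment is None:
        assignment = np.tile(np.arange(c, dtype=np.int64)[:, None], (1, n))
    assignment = assignment.copy()
    sl = perm.window_slice(*window)

    data_w = perm.rates[:, :, sl].astype(np.float64)
    row_means = data_w.reshape(n, -1).mean(axis=1)
    A = data_w - row_means[:, None, None]
    obs_w = obs.rates[:, :, sl].reshape(n, -1)
    Cobs = np.cov(obs_w)
    Cmat = np.cov(A.reshape(n, -1))
    tss = np.sum((Cobs - Cobs.mean()) ** 2)
    if tss <= 0:
        raise ValueError("observed covariance has zero variance; similarity undefined")
    max_swaps = cfg.max_swaps if cfg.max_swaps is not None else 200 * n * c

    proposals, accepted, ssd = _greedy_match(
        A, Cmat, Cobs, tss, cfg.similarity_threshold, max_swaps,
        assignment, int(seed) % (2**31),
    )
    similarity = 1.0 - ssd / tss
    return assignment, similarity, {
        "proposals": int(proposals),
        "accepted": int(accepted),
        "similarity": float(similarity),
        "converged": bool(similarity >= cfg.similarity_threshold),
    }


def _apply_assignment(pop: PopulationActivity, assignment: np.ndarray) -> PopulationActivity:
    """Population whose slot c holds the original condition assignment[c, n]."""
    n, c, _ = pop.rates.shape
    rates = np.empty_like(pop.rates)
    for i in range(n):
        rates[i] = pop.rates[i, assignment[:, i]]
    return PopulationActivity(
        rates=rates,
        time_ms=pop.time_ms.copy(),
        dt=pop.dt,
        events=dict(pop.events),
        condition_meta=dict(pop.condition_meta),
        generator=pop.generator + "+matched",
    )


def run_cmpt(
    pop: PopulationActivity,
    jpca_cfg: JpcaConfig = None,
    cmpt_cfg: CmptConfig = None,
) -> CmptResult:
    """Full covariance-matched permutation test on one population."""
    jpca_cfg = jpca_cfg or JpcaConfig()
    cmpt_cfg = cmpt_cfg or CmptConfig()
    window = resolve_window(pop, jpca_cfg)
    observed = _statistic(jpca_analyze(pop, jpca_cfg), cmpt_cfg.statistic)

    rng = np.random.default_rng(cmpt_cfg.seed)
    null_rgrs, sims, assignments, swap_stats = [], [], [], []
    n_failed = 0
    for _ in range(cmpt_cfg.n_reps):
        _, assignment0 = permute_assignments(pop, rng)
        assignment, similarity, info = match_covariance(
            pop_with_assignment(pop, assignment0), pop, cmpt_cfg, window,
            assignment=assignment0, seed=int(rng.integers(2**31)),
        )
        if not info["converged"]:
            n_failed += 1
            warnings.warn(
                f"CMPT repetition discarded: similarity {similarity:.3f} "
                f"below threshold after {info['proposals']} proposals"
            )
            continue
        matched = _apply_assignment(pop, assignment)
        null_rgrs.append(_statistic(jpca_analyze(matched, jpca_cfg), cmpt_cfg.statistic))
        sims.append(similarity)
        assignments.append(assignment)
        swap_stats.append((info["proposals"], info["accepted"]))
    if not null_rgrs:
        raise RuntimeError("all CMPT repetitions failed covariance matching")
    null_rgrs = np.asarray(null_rgrs)
    p = float(np.mean(null_rgrs >= observed))
    sd = null_rgrs.std(ddof=1) if len(null_rgrs) > 1 else 0.0
    effect = float((observed - null_rgrs.mean()) / sd) if sd > 0 else np.inf
    return CmptResult(
        observed_rgr=float(observed),
        null_rgrs=null_rgrs,
        p_value=p,
        effect_size=effect,
        similarity_achieved=np.asarray(sims),
        assignments=np.asarray(assignments),
        n_failed=n_failed,
        swap_stats=np.asarray(swap_stats),
    )


def pop_with_assignment(pop: PopulationActivity, assignment: np.ndarray) -> PopulationActivity:
    """Alias of the internal reassignment used when seeding the matcher."""
    return _apply_assignment(pop, assignment)


def _sort_assignment_rows(assignment: np.ndarray) -> np.ndarray:
    """Conservative row sort: row labeled c gets the row where c is most common.

    Greedy maximum matching on the per-row condition counts; leftover rows
    fill the remaining slots in order.
    """
    c, n = assignment.shape
    counts = np.stack([(assignment == cond).sum(axis=1) for cond in range(c)], axis=1)  # (row, cond)
    taken = np.zeros(c, dtype=bool)
    order = np.full(c, -1)
    for cond in range(c):
        masked = np.where(taken, -1, counts[:, cond])
        row = int(np.argmax(masked))
        order[cond] = row
        taken[row] = True
    return assignment[order]


def unshuffle_check(result: CmptResult) -> tuple:
    """Correlation of null RGR with the retained-assignment fraction.

    Each repetition's assignment matrix is row-sorted so that the most common
    condition in a row maps to that row's label (the most conservative
    comparison); the retained fraction is the share of entries equal to the
    identity. Returns (pearson r, two-sided p) and stores both plus the
    per-repetition fractions on the result.
    """
    if len(result.assignments) < 3:
        raise ValueError("need at least 3 repetitions to correlate")
    c = result.assignments.shape[1]
    ident = np.arange(c)[:, None]
    retained = np.array(
        [np.mean(_sort_assignment_rows(a) == ident) for a in result.assignments]
    )
    if retained.std() == 0 or result.null_rgrs.std() == 0:
        warnings.warn("zero variance in retained fractions or null RGRs; correlation undefined")
        result.retained_fractions = retained
        return np.nan, np.nan
    r, p = stats.pearsonr(retained, result.null_rgrs)
    result.unshuffle_r, result.unshuffle_p = float(r), float(p)
    result.retained_fractions = retained
    return float(r), float(p)


def subset_grid(
    pop: PopulationActivity,
    neuron_counts,
    condition_counts,
    n_reps: int = 100,
    seed: int = 0,
    jpca_cfg: JpcaConfig = None,
    cmpt_cfg: CmptConfig = None,
):
    """CMPT over random neuron/condition subsets (sensitivity map).

    For every grid cell, each repetition draws a fresh random subset, computes
    the observed RGR on it and one covariance-matched null RGR; the cell's
    p-value is the fraction of repetitions whose null reached its observed
    value, and the effect size compares the mean observed RGR with the null
    distribution. Returns (p_map, effect_map) of shape
    (len(neuron_counts), len(condition_counts)); cells with fewer than 2
    conditions are NaN.
    """
    jpca_cfg = jpca_cfg or JpcaConfig()
    base_cmpt = cmpt_cfg or CmptConfig()
    rng = np.random.default_rng(seed)
    neuron_counts = list(neuron_counts)
    condition_counts = list(condition_counts)
    p_map = np.full((len(neuron_counts), len(condition_counts)), np.nan)
    e_map = np.full_like(p_map, np.nan)
    for i, nn in enumerate(neuron_counts):
        for j, nc in enumerate(condition_counts):
            if nc < 2 or nn < jpca_cfg.d or nn > pop.n_neurons or nc > pop.n_conditions:
                continue
            obs_vals, null_vals = [], []
            for _ in range(n_reps):
                sub = pop.subset(
                    neurons=rng.choice(pop.n_neurons, nn, replace=False),
                    conditions=rng.choice(pop.n_conditions, nc, replace=False),
                )
                window = resolve_window(sub, jpca_cfg)
                try:
                    obs = _statistic(jpca_analyze(sub, jpca_cfg), base_cmpt.statistic)
                    _, a0 = permute_assignments(sub, rng)
                    a, sim, info = match_covariance(
                        _apply_assignment(sub, a0), sub, base_cmpt, window,
                        assignment=a0, seed=int(rng.integers(2**31)),
                    )
                    if not info["converged"]:
                        continue
                    null = _statistic(jpca_analyze(_apply_assignment(sub, a), jpca_cfg),
                                      base_cmpt.statistic)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                obs_vals.append(obs)
                null_vals.append(null)
            if len(null_vals) >= 3:
                obs_vals, null_vals = np.asarray(obs_vals), np.asarray(null_vals)
                p_map[i, j] = np.mean(null_vals >= obs_vals)
                sd = null_vals.std(ddof=1)
                if sd > 0:
                    e_map[i, j] = (obs_vals.mean() - null_vals.mean()) / sd
    return p_map, e_map
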