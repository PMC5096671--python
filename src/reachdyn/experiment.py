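"""Experiment configuration and end-to-end reproduction drivers.

Every stochastic stage takes an explicit seed; a driver run is fully
determined by its :class:`ExperimentConfig`, which round-trips through YAML.
Drivers write JSON/CSV summaries into an output directory and return a
:class:`RunRecord` with all metrics and warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cmpt import CmptConfig, run_cmpt, subset_grid, unshuffle_check
from .dynamical import DynamicalParams, simulate_dynamical
from .jpca import JpcaConfig, jpca_analyze
from .population import PopulationActivity
from .representational import (
    ComplexKinematicParams,
    RepresentationalParams,
    detect_neural_movement_onset,
    latency_sweep,
    simulate_complex_kinematic,
    simulate_representational,
)
from .rnn import TrainingConfig, export_population, init_network, make_trials, train
from .task import bell_profile, kinematic_traces, make_targets

__all__ = ["ExperimentConfig", "RunRecord", "run_experiment", "build_population"]

SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Declarative description of one reproduction experiment."""

    experiment: str = "rotation_metrics"   # driver name
    generator: str = "representational"    # representational|dynamical|complex_kinematic|rnn
    n_conditions: int = 13
    seed: int = 0
    n_seeds: int = 1
    generator_params: dict = field(default_factory=dict)
    jpca: dict = field(default_factory=dict)
    cmpt: dict = field(default_factory=dict)
    sweep_latency_sds: list = field(default_factory=lambda: [0, 24, 48, 72, 96])
    sweep_movement_sds: list = field(default_factory=lambda: [28, 56, 84])
    sweep_reps: int = 3
    grid_neurons: list = field(default_factory=lambda: [20, 60, 120])
    grid_conditions: list = field(default_factory=lambda: [3, 7, 13])
    out_dir: str = "results"
    schema: int = SCHEMA_VERSION

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("schema", 0) != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {data.get('schema')}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunRecord:
    config_hash: str
    version: str
    experiment: str
    metrics: dict
    timings: dict
    warnings: list

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "experiment": self.experiment,
                    "metrics": self.metrics,
                    "timings": self.timings,
                    "warnings": self.warnings,
                },
                indent=2,
                default=float,
            )
        )


def build_population(cfg: ExperimentConfig, seed: int = None) -> PopulationActivity:
    """Simulate (or train and export) the population named by the config."""
    seed = cfg.seed if seed is None else seed
    task = make_targets(cfg.n_conditions)
    gp = dict(cfg.generator_params)
    if cfg.generator == "representational":
        pop = simulate_representational(RepresentationalParams(**gp), task, seed=seed)
        detect_neural_movement_onset(pop)
    elif cfg.generator == "dynamical":
        pop = simulate_dynamical(task, DynamicalParams(**gp), seed=seed)
    elif cfg.generator == "complex_kinematic":
        duration = gp.pop("movement_duration", 400.0)
        kin = kinematic_traces(task, bell_profile(duration, 10.0, radius=task.reach_radius), 10.0)
        pop = simulate_complex_kinematic(ComplexKinematicParams(**gp), task, kin, seed=seed)
        detect_neural_movement_onset(pop)
    elif cfg.generator == "rnn":
        tcfg = TrainingConfig(seed=seed, **gp)
        model = init_network(seed=seed)
        trials = make_trials(task, tcfg)
        trained, info = train(model, trials, tcfg)
        pop = export_population(trained, trials, delay=800.0)
        pop.params["normalized_error"] = info["normalized_error"]
    else:
        raise ValueError(f"unknown generator {cfg.generator!r}")
    return pop


def run_experiment(cfg: ExperimentConfig) -> RunRecord:
    """Run one driver end-to-end, writing artifacts into ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, metrics, caught = {}, {}, []
    jcfg = JpcaConfig(**cfg.jpca)
    rng = np.random.default_rng(cfg.seed)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        t0 = time.time()
        if cfg.experiment == "rotation_metrics":
            rows = []
            for _ in range(cfg.n_seeds):
                pop = build_population(cfg, seed=int(rng.integers(2**31)))
                res = jpca_analyze(pop, jcfg)
                rows.append(res.metrics())
            df = pd.DataFrame(rows)
            df.to_csv(out / f"{cfg.generator}_rotation_metrics.csv", index=False)
            metrics = {
                "rgr_all_mean": float(df["rgr_all"].mean()),
                "circularity_mean": float(df["circularity"].mean()),
                "var_two_planes_mean": float(
                    df["variance_per_plane"].apply(lambda v: v[0] + v[1]).mean()
                ),
            }
        elif cfg.experiment == "cmpt":
            pop = build_population(cfg)
            res = run_cmpt(pop, jcfg, CmptConfig(seed=cfg.seed, **cfg.cmpt))
            r, p = unshuffle_check(res)
            metrics = {
                "observed_rgr": res.observed_rgr,
                "p_value": res.p_value,
                "effect_size": res.effect_size,
                "similarity_mean": float(res.similarity_achieved.mean()),
                "n_failed": res.n_failed,
                "unshuffle_r": r,
                "unshuffle_p": p,
            }
            pd.DataFrame({"null_rgr": res.null_rgrs}).to_csv(
                out / f"{cfg.generator}_cmpt_null.csv", index=False
            )
        elif cfg.experiment == "latency_sweep":
            grid = latency_sweep(
                cfg.sweep_latency_sds, cfg.sweep_movement_sds,
                make_targets(cfg.n_conditions), reps=cfg.sweep_reps, seed=cfg.seed,
            )
            pd.DataFrame(
                grid, index=cfg.sweep_latency_sds, columns=cfg.sweep_movement_sds
            ).to_csv(out / "latency_sweep_rgr.csv")
            metrics = {"grid_max": float(np.nanmax(grid)), "grid_min": float(np.nanmin(grid))}
        elif cfg.experiment == "subset_grid":
            pop = build_population(cfg)
            p_map, e_map = subset_grid(
                pop, cfg.grid_neurons, cfg.grid_conditions,
                n_reps=cfg.cmpt.get("n_reps", 100), seed=cfg.seed,
                jpca_cfg=jcfg, cmpt_cfg=CmptConfig(seed=cfg.seed, **cfg.cmpt),
            )
            for name, m in (("pmap", p_map), ("effectmap", e_map)):
                pd.DataFrame(m, index=cfg.grid_neurons, columns=cfg.grid_conditions).to_csv(
                    out / f"{cfg.generator}_subset_{name}.csv"
                )
            metrics = {"p_min": float(np.nanmin(p_map)), "effect_max": float(np.nanmax(e_map))}
        else:
            raise ValueError(f"unknown experiment {cfg.experiment!r}")
        timings[cfg.experiment] = time.time() - t0
        caught = [str(w.message) for w in wlist]

    record = RunRecord(
        config_hash=cfg.hash(),
        version=__version__,
        experiment=cfg.experiment,
        metrics=metrics,
        timings=timings,
        warnings=caught,
    )
    record.to_json(out / f"{cfg.experiment}_{cfg.generator}_record.json")
    return record
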