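"""The firing-rate container shared by all simulators and analyses.

A :class:`PopulationActivity` is a trial-averaged firing-rate tensor of shape
(neurons, conditions, time) on a uniform time axis in ms, with named event
markers (at minimum the go cue) and optional per-neuron ground-truth metadata
from the generator (latency, preferred angle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["PopulationActivity", "save_population", "load_population"]

_SCHEMA_VERSION = 1


@dataclass
class PopulationActivity:
    rates: np.ndarray            # (neurons, conditions, time)
    time_ms: np.ndarray          # (time,), uniform, relative to the go cue
    dt: float                    # ms
    events: dict = field(default_factory=dict)
    neuron_meta: dict = field(default_factory=dict)    # per-neuron arrays
    condition_meta: dict = field(default_factory=dict)  # e.g. target_angles
    generator: str = ""
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (neurons, conditions, time)")
        if self.time_ms.size != self.rates.shape[2]:
            raise ValueError("time axis length must match rates' last axis")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if self.time_ms.size > 1:
            steps = np.diff(self.time_ms)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniform")
        for name, t in self.events.items():
            if t < self.time_ms[0] - 1e-9 or t > self.time_ms[-1] + 1e-9:
                raise ValueError(f"event {name!r} at {t} ms lies outside the time axis")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[1]

    @property
    def n_times(self) -> int:
        return self.rates.shape[2]

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (ms)."""
        return int(np.argmin(np.abs(self.time_ms - t)))

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Slice covering ``t_start <= t <= t_end`` (inclusive, ms)."""
        i0 = int(np.searchsorted(self.time_ms, t_start - 1e-9))
        i1 = int(np.searchsorted(self.time_ms, t_end + 1e-9))
        if i1 - i0 < 2:
            raise ValueError("window selects fewer than 2 samples")
        return slice(i0, i1)

    def subset(self, neurons=None, conditions=None) -> "PopulationActivity":
        """A view-copy restricted to given neuron / condition indices."""
        neurons = np.arange(self.n_neurons) if neurons is None else np.asarray(neurons)
        conditions = (
            np.arange(self.n_conditions) if conditions is None else np.asarray(conditions)
        )
        meta = {k: np.asarray(v)[neurons] for k, v in self.neuron_meta.items()}
        cmeta = {k: np.asarray(v)[conditions] for k, v in self.condition_meta.items()}
        return PopulationActivity(
            rates=self.rates[np.ix_(neurons, conditions)].copy(),
            time_ms=self.time_ms.copy(),
            dt=self.dt,
            events=dict(self.events),
            neuron_meta=meta,
            condition_meta=cmeta,
            generator=self.generator,
            seed=self.seed,
            params=dict(self.params),
        )


def save_population(path: str, pop: PopulationActivity) -> None:
    """Write a population to HDF5 (``.h5``/``.hdf5``) or NPZ (``.npz``)."""
    path = str(path)
    if path.endswith(".npz"):
        np.savez(
            path,
            rates=pop.rates,
            time_ms=pop.time_ms,
            dt=pop.dt,
            events=json.dumps(pop.events),
            neuron_meta=json.dumps({k: np.asarray(v).tolist() for k, v in pop.neuron_meta.items()}),
            condition_meta=json.dumps(
                {k: np.asarray(v).tolist() for k, v in pop.condition_meta.items()}
            ),
            generator=pop.generator,
            seed=-1 if pop.seed is None else pop.seed,
            params=json.dumps(pop.params),
            schema=_SCHEMA_VERSION,
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=pop.rates)
        f.create_dataset("time_ms", data=pop.time_ms)
        f.attrs["dt"] = pop.dt
        f.attrs["events"] = json.dumps(pop.events)
        f.attrs["generator"] = pop.generator
        f.attrs["seed"] = -1 if pop.seed is None else pop.seed
        f.attrs["params"] = json.dumps(pop.params)
        f.attrs["schema"] = _SCHEMA_VERSION
        nm = f.create_group("neuron_meta")
        for k, v in pop.neuron_meta.items():
            nm.create_dataset(k, data=np.asarray(v))
        cm = f.create_group("condition_meta")
        for k, v in pop.condition_meta.items():
            cm.create_dataset(k, data=np.asarray(v))


def load_population(path: str) -> PopulationActivity:
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            for key in ("rates", "time_ms", "dt"):
                if key not in z:
                    raise KeyError(f"population file is missing required field {key!r}")
            seed = int(z["seed"])
            return PopulationActivity(
                rates=z["rates"],
                time_ms=z["time_ms"],
                dt=float(z["dt"]),
                events=json.loads(str(z["events"])),
                neuron_meta={k: np.asarray(v) for k, v in json.loads(str(z["neuron_meta"])).items()},
                condition_meta={
                    k: np.asarray(v) for k, v in json.loads(str(z["condition_meta"])).items()
                },
                generator=str(z["generator"]),
                seed=None if seed < 0 else seed,
                params=json.loads(str(z["params"])),
            )
    with h5py.File(path, "r") as f:
        if "dt" not in f.attrs:
            raise KeyError("population file is missing required attribute 'dt'")
        seed = int(f.attrs.get("seed", -1))
        return PopulationActivity(
            rates=f["rates"][...],
            time_ms=f["time_ms"][...],
            dt=float(f.attrs["dt"]),
            events=json.loads(f.attrs.get("events", "{}")),
            neuron_meta={k: f["neuron_meta"][k][...] for k in f.get("neuron_meta", {})},
            condition_meta={k: f["condition_meta"][k][...] for k in f.get("condition_meta", {})},
            generator=str(f.attrs.get("generator", "")),
            seed=None if seed < 0 else seed,
            params=json.loads(f.attrs.get("params", "{}")),
        )
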