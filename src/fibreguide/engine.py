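"""Simulation orchestration: configuration, stepping, snapshots.

The per-step update order is fixed: (1) motility kicks and pairwise
forces are computed from the state at ``t``; (2) the fibre field is
sampled at each cell centre and the guidance operator built; (3) all
positions update synchronously; (4) the fibre field is remodelled from
the updated positions and averaged velocities; (5) the proliferation
sweep runs.  Identical configuration and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .fibre_field import FibreField
from .initial_conditions import InitialCondition, preset
from .mechanics import (CellPopulation, ModelParams, attempt_divisions,
                        euler_step_positions)
from .remodelling import remodel_field

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """A full experiment description: parameters, initial state, output."""

    params: ModelParams = dc_field(default_factory=ModelParams)
    initial: InitialCondition = dc_field(default_factory=InitialCondition)
    snapshot_interval_min: float = 60.0
    outdir: str | None = None

    def validate(self) -> None:
        self.params.validate()
        dt = self.params.dt
        cad = self.snapshot_interval_min
        if cad <= 0 or abs(cad / dt - round(cad / dt)) > 1e-9:
            raise ValueError(
                "snapshot cadence must be a positive multiple of dt")
        tf = self.params.T_final
        if abs(tf / dt - round(tf / dt)) > 1e-9:
            raise ValueError("T_final must be a multiple of dt")

    def with_params(self, **kwargs) -> "SimulationConfig":
        return replace(self, params=replace(self.params, **kwargs))


class Simulation:
    """Mutable simulation state plus the stepping loop."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.params = config.params
        positions, self.field = config.initial.build(self.params)
        hist_steps = int(round(self.params.m / self.params.dt))
        self.population = CellPopulation(
            positions, self.params.domain_length,
            history_steps=hist_steps, dt=self.params.dt)
        self.rng = np.random.default_rng(self.params.seed)

    @property
    def time_min(self) -> float:
        return self.population.time_min

    def step(self) -> None:
        p, f = self.params, self.field
        euler_step_positions(self.population, f, p, self.rng)
        memory = self.population.velocity_memory(p.m)
        remodel_field(f, self.population, memory, p)
        attempt_divisions(self.population, p, self.rng)

    def run_until(self, t_min: float, callback=None) -> None:
        """Advance to ``t_min``, invoking ``callback(sim)`` after each
        step if given."""
        n_steps = int(round((t_min - self.time_min) / self.params.dt))
        for _ in range(n_steps):
            self.step()
            if callback is not None:
                callback(self)


@dataclass
class Trajectory:
    """Handle to a finished run: snapshot manifest plus final state."""

    outdir: Path
    manifest: list
    simulation: Simulation


def write_snapshot(population: CellPopulation, field: FibreField,
                   time_min: float, outdir) -> dict:
    """Write one cell CSV + field HDF5 snapshot pair; return its
    manifest entry.  The field's trace bounds are validated on write."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    field.validate()
    tag = f"{int(round(time_min)):07d}"
    cells_name = f"cells_t{tag}.csv"
    field_name = f"field_t{tag}.h5"
    population.to_dataframe(time_min).to_csv(outdir / cells_name, index=False)
    field.to_hdf5(outdir / field_name, time_min)
    return {"time_min": float(time_min), "cells": cells_name,
            "field": field_name}


def read_snapshot(outdir, entry: dict):
    """Read back one manifest entry as ``(DataFrame, FibreField)``."""
    import pandas as pd

    outdir = Path(outdir)
    cells = pd.read_csv(outdir / entry["cells"])
    field = FibreField.from_hdf5(outdir / entry["field"])
    return cells, field


def load_manifest(outdir) -> list:
    with open(Path(outdir) / "manifest.json") as f:
        return json.load(f)


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run a configured experiment, writing snapshots at the cadence.

    Snapshots are written at t = 0 and every ``snapshot_interval_min``
    up to and including ``T_final``.  A JSON manifest indexes them.
    """
    config.validate()
    if config.outdir is None:
        raise ValueError("run_simulation needs an output directory")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = Simulation(config)
    p = config.params
    manifest = [write_snapshot(sim.population, sim.field, 0.0, outdir)]
    n_steps = int(round(p.T_final / p.dt))
    cadence = int(round(config.snapshot_interval_min / p.dt))
    t0 = _time.perf_counter()
    for k in range(1, n_steps + 1):
        sim.step()
        if k % cadence == 0:
            manifest.append(
                write_snapshot(sim.population, sim.field, k * p.dt, outdir))
            log.info("t = %.0f min  N = %d  mean trace = %.4f  (%.1f s)",
                     k * p.dt, sim.population.n,
                     float(sim.field.trace().mean()),
                     _time.perf_counter() - t0)
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return Trajectory(outdir=outdir, manifest=manifest, simulation=sim)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_PARAM_KEYS = {f.name for f in ModelParams.__dataclass_fields__.values()}
_IC_KEYS = {"n_cells", "field_kind", "total_fraction", "anisotropy",
            "major_angle_deg"}
_OUTPUT_KEYS = {"snapshot_interval_min", "outdir"}


def load_config(path) -> SimulationConfig:
    """Parse and validate a TOML experiment configuration.

    Recognised tables: ``[params]`` (any model parameter), ``[initial]``
    (cell count and fibre-bed spec) and ``[output]``; a top-level
    ``preset`` key seeds the configuration from a named preset before
    overrides apply.  An empty file yields the default parameters on
    the small (360 um) domain.  Unknown keys are rejected by name.
    """
    import tomllib

    with open(path, "rb") as f:
        raw = tomllib.load(f)
    known_top = {"preset", "variant", "params", "initial", "output"}
    for key in raw:
        if key not in known_top:
            raise ValueError(f"unknown configuration key {key!r}")
    if "preset" in raw:
        config = preset(raw["preset"], variant=raw.get("variant"))
    else:
        config = SimulationConfig()
    params_tbl = raw.get("params", {})
    for key in params_tbl:
        if key not in _PARAM_KEYS:
            raise ValueError(f"unknown parameter key {key!r}")
    if params_tbl:
        config = config.with_params(**params_tbl)
    ic_tbl = raw.get("initial", {})
    for key in ic_tbl:
        if key not in _IC_KEYS:
            raise ValueError(f"unknown initial-condition key {key!r}")
    if ic_tbl:
        config = replace(config, initial=replace(config.initial, **ic_tbl))
    out_tbl = raw.get("output", {})
    for key in out_tbl:
        if key not in _OUTPUT_KEYS:
            raise ValueError(f"unknown output key {key!r}")
    if out_tbl:
        config = replace(config, **out_tbl)
    config.validate()
    return config
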