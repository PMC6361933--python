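"""Plain-text writers/readers for simulation and analysis artifacts."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import SimulationConfig, SimulationResult

__all__ = [
    "write_raster",
    "read_raster",
    "write_series",
    "read_series",
    "write_config",
    "read_config",
    "write_run",
]


def write_raster(raster: np.ndarray, path: "str | Path") -> None:
    """Spike events as ``neuron_id<TAB>step`` (0-based recorded steps)."""
    with open(path, "w") as fh:
        fh.write("neuron\tstep\n")
        for neuron, step in raster:
            fh.write(f"{neuron}\t{step}\n")


def read_raster(path: "str | Path") -> np.ndarray:
    return np.loadtxt(path, skiprows=1, dtype=np.int64, ndmin=2)


def write_series(series: np.ndarray, path: "str | Path") -> None:
    """One-column text series."""
    np.savetxt(path, np.asarray(series), fmt="%.8g")


def read_series(path: "str | Path") -> np.ndarray:
    return np.loadtxt(path)


def write_config(config: SimulationConfig, path: "str | Path") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)


def read_config(path: "str | Path") -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig(**yaml.safe_load(fh))


def write_run(result: SimulationResult, outdir: "str | Path") -> None:
    """Persist a simulation run: raster, S(t), config and a summary line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(result.raster, outdir / "raster.tsv")
    write_series(result.S, outdir / "S.txt")
    write_config(result.config, outdir / "config.yaml")
    summary = {
        "n_neurons": int(result.v_trace.shape[1]),
        "transient_steps": result.config.transient_steps,
        "record_steps": result.config.record_steps,
        "rate_exc_spks_per_s": result.rate_exc,
        "n_spikes": int(len(result.raster)),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
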