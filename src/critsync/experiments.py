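"""Experiment orchestration: calibration curves, single cells, sweeps.

A "cell" is one point of the (kappa, eta) control plane: rich-club
connection probability times inhibitory-local-hub probability, for case 1
(inhibitory global hubs) or case 2 (excitatory global hubs).  Each cell
runs the full pipeline — build network, assign types, simulate, DFA of
the global state, lability of synchronization — under reproducible
per-cell, per-run seeds spawned from a base seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as nw
from .dfa import DFAResult, dfa_exponent
from .dynamics import SimulationConfig, SimulationResult, firing_rate, simulate
from .synchrony import LabilityResult, fit_powerlaw_delta, lability_pipeline

__all__ = [
    "PhaseDiagram",
    "CellResult",
    "build_network",
    "run_cell",
    "sweep",
    "lability_grid",
    "calibration_curves",
]


@dataclass
class CellResult:
    case: int
    kappa: float
    eta: float
    seed: int
    alpha: float
    rate: float
    dfa: DFAResult
    lability: "LabilityResult | None"


@dataclass
class PhaseDiagram:
    kappa_grid: np.ndarray
    eta_grid: np.ndarray
    alpha_mean: np.ndarray  # (len(kappa_grid), len(eta_grid))
    n_runs: int
    case: int
    seeds: np.ndarray  # (n_kappa, n_eta, n_runs)

    def to_frame(self) -> pd.DataFrame:
        """Heatmap as a DataFrame: rows = kappa, columns = eta."""
        return pd.DataFrame(
            self.alpha_mean,
            index=pd.Index(self.kappa_grid, name="kappa"),
            columns=pd.Index(self.eta_grid, name="eta"),
        )


def _cell_rng(base_seed: int, case: int, kappa: float, eta: float, run: int):
    """Reproducible per-(cell, run) generator."""
    key = [int(base_seed), int(case), int(round(kappa * 1000)),
           int(round(eta * 1000)), int(run)]
    return np.random.default_rng(key)


def build_network(
    case: int,
    kappa: float,
    eta: float,
    rng: np.random.Generator,
    n_nodes: int = 625,
    local_hub_inhibitory: "list[int] | None" = None,
) -> nw.HierarchicalNetwork:
    """Base construction + rich club + neuron types for one cell."""
    if n_nodes == 25:
        net = nw.build_base_network(1)
    elif n_nodes == 125:
        net = nw.build_base_network(2)
    elif n_nodes == 625:
        net = nw.assemble_replicas(nw.build_base_network(2))
    else:
        raise ValueError("n_nodes must be 25, 125 or 625")
    net = nw.connect_rich_club(net, kappa, rng)
    return nw.assign_neuron_types(
        net, case, eta, rng, local_hub_inhibitory=local_hub_inhibitory
    )


def run_cell(
    case: int,
    kappa: float,
    eta: float,
    config: SimulationConfig,
    seed: int,
    n_nodes: int = 625,
    with_lability: bool = False,
    local_hub_inhibitory: "list[int] | None" = None,
) -> CellResult:
    """One full pipeline pass with a single seed."""
    rng = _cell_rng(seed, case, kappa, eta, 0)
    net = build_network(case, kappa, eta, rng, n_nodes, local_hub_inhibitory)
    result = simulate(net, config, rng)
    dfa = dfa_exponent(result.S)
    lab = lability_pipeline(result, net) if with_lability else None
    return CellResult(
        case=case, kappa=kappa, eta=eta, seed=seed,
        alpha=dfa.alpha, rate=firing_rate(result), dfa=dfa, lability=lab,
    )


def sweep(
    case: int,
    kappa_grid: np.ndarray,
    eta_grid: np.ndarray,
    n_runs: int = 50,
    base_seed: int = 0,
    config: "SimulationConfig | None" = None,
) -> PhaseDiagram:
    """Mean DFA exponent per (kappa, eta) cell over independent runs.

    Per-cell seeds are derived from ``base_seed`` and the cell coordinates,
    so any pixel can be regenerated in isolation.  A failed run (numerical
    abort) is recorded as NaN and skipped in the mean.
    """
    config = config or SimulationConfig()
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    eta_grid = np.asarray(eta_grid, dtype=float)
    if kappa_grid.min() < 0 or kappa_grid.max() > 1 or eta_grid.min() < 0 or eta_grid.max() > 1:
        raise ValueError("grids must lie within [0, 1]")
    alpha = np.full((kappa_grid.size, eta_grid.size), np.nan)
    seeds = np.zeros((kappa_grid.size, eta_grid.size, n_runs), dtype=np.int64)
    for i, kappa in enumerate(kappa_grid):
        for j, eta in enumerate(eta_grid):
            vals = []
            for run in range(n_runs):
                rng = _cell_rng(base_seed, case, kappa, eta, run)
                seeds[i, j, run] = run
                try:
                    net = build_network(case, kappa, eta, rng)
                    res = simulate(net, config, rng)
                    vals.append(dfa_exponent(res.S).alpha)
                except FloatingPointError:
                    vals.append(np.nan)
            alpha[i, j] = np.nanmean(vals)
    return PhaseDiagram(
        kappa_grid=kappa_grid, eta_grid=eta_grid, alpha_mean=alpha,
        n_runs=n_runs, case=case, seeds=seeds,
    )


def lability_grid(
    case: int,
    kappa_values: np.ndarray,
    eta_values: np.ndarray,
    n_runs: int = 100,
    base_seed: int = 0,
    config: "SimulationConfig | None" = None,
) -> pd.DataFrame:
    """Pooled lability exponent per (kappa, eta) cell.

    Lability series from ``n_runs`` independent runs are pooled before the
    density and bounded-ML exponent fit, mirroring how the distributions
    are accumulated over repeated realizations.
    """
    config = config or SimulationConfig()
    rows = []
    for kappa in np.atleast_1d(kappa_values):
        for eta in np.atleast_1d(eta_values):
            ells = []
            for run in range(n_runs):
                rng = _cell_rng(base_seed, case, kappa, eta, run)
                net = build_network(case, float(kappa), float(eta), rng)
                res = simulate(net, config, rng)
                ells.append(lability_pipeline(res, net, fit=False).ell)
            ell = np.concatenate(ells)
            try:
                delta, mse = fit_powerlaw_delta(ell)
            except ValueError:
                delta, mse = np.nan, np.nan
            rows.append(
                {"case": case, "kappa": float(kappa), "eta": float(eta),
                 "delta": delta, "mse": mse, "n_runs": n_runs,
                 "n_positive": int((ell > 0).sum())}
            )
    return pd.DataFrame(rows)


def calibration_curves(
    h_values: "list[float]",
    w_grid_base: np.ndarray,
    n_runs: int = 3,
    base_seed: int = 0,
    case: int = 1,
    kappa: float = 0.5,
    eta: float = 0.0,
    config: "SimulationConfig | None" = None,
) -> pd.DataFrame:
    """Firing rate versus synaptic weight for several time resolutions.

    For each resolution h the base weight grid (stated at h = 0.1 ms) is
    rescaled by 0.1/h, so that a collapse of the curves onto each other
    confirms that the synaptic impulse w*h is what matters.  Returns a
    tidy frame with columns (h, w, w_scaled, rate).
    """
    config = config or SimulationConfig()
    rows = []
    for h in h_values:
        scale = 0.1 / h
        for w_base in np.asarray(w_grid_base, dtype=float):
            w = w_base * scale
            cfg = dataclasses.replace(config, h=h, weight=w)
            rates = []
            for run in range(n_runs):
                rng = _cell_rng(base_seed, case, kappa, eta, run)
                net = build_network(case, kappa, eta, rng)
                rates.append(firing_rate(simulate(net, cfg, rng)))
            rows.append({"h": h, "w": w, "w_scaled": w_base,
                         "rate": float(np.mean(rates))})
    return pd.DataFrame(rows)
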