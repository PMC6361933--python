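"""Izhikevich spiking dynamics on a hierarchical network.

Each neuron follows the two-variable quadratic integrate-and-fire model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I + s
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

integrated with the midpoint 2nd-order Runge-Kutta scheme at a default
resolution of h = 0.1 ms.  ``I`` is a noisy thalamic drive of magnitude 5
for excitatory and 2 for inhibitory neurons (a calibrated mean fraction
plus diffusion-consistent Gaussian noise; see ``SimulationConfig``);
``s`` sums the synaptic kicks of presynaptic neurons that fired on the
previous step (+w excitatory, -w inhibitory, delivered for a single
step).  Parameter
heterogeneity follows the standard convention: per neuron one uniform
draw ``r`` in [0, 1] interpolates excitatory cells between regular
spiking (r=0) and chattering (r=1), and inhibitory cells between
low-threshold spiking and fast spiking.

The global state is the mean membrane potential S(t) = (1/N) sum_i v_i(t),
recorded for ``record_steps`` steps after a transient of
``transient_steps`` steps is discarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .network import HierarchicalNetwork

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "NeuronParams",
    "SimulationConfig",
    "SimulationResult",
    "make_neuron_params",
    "derivatives",
    "apply_reset",
    "rk2_step",
    "simulate",
    "firing_rate",
    "calibrate_weight",
]

SPIKE_THRESHOLD = 30.0  # mV


@dataclass
class NeuronParams:
    """Per-neuron Izhikevich parameters (arrays over the population)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    i_scale: np.ndarray  # thalamic noise magnitude (std of the Gaussian drive)
    r: np.ndarray  # static heterogeneity draw in [0, 1]
    is_excitatory: np.ndarray


@dataclass
class SimulationConfig:
    h: float = 0.1  # integration step, ms
    transient_steps: int = 8000
    record_steps: int = 10_000
    weight: float = 40.0  # synaptic magnitude, mV
    #: The thalamic drive of neuron i at step t is
    #: I_t = drive_mean * I_i + noise_scale * I_i * xi_t / sqrt(h),
    #: with I_i the printed magnitudes (5 excitatory, 2 inhibitory) and xi_t
    #: i.i.d. standard normal.  The 1/sqrt(h) factor makes the stochastic
    #: part diffusion-consistent: the drive accumulated per millisecond is
    #: independent of the integration step, which is what lets rate-vs-
    #: weight curves at different resolutions collapse onto each other when
    #: w is rescaled by the step-size ratio.  The two dimensionless
    #: constants are fixed once by calibration against the published
    #: operating point (mean excitatory rate crossing 5 spks/s at w = 40 mV
    #: and h = 0.1 ms, in the 1/f regime of the inhibitory-global-hub
    #: configuration): the mean fraction keeps neurons excitable a few mV
    #: below the saddle-node so that synaptic kicks (h*w = 4 mV) can
    #: propagate avalanches, while the noise supplies the spontaneous
    #: ignitions.
    drive_mean: float = 0.65
    noise_scale: float = 0.10

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.transient_steps < 0 or self.record_steps < 1:
            raise ValueError("invalid step counts")

    @property
    def recorded_duration_s(self) -> float:
        return self.record_steps * self.h / 1000.0


@dataclass
class SimulationResult:
    raster: np.ndarray  # (n_events, 2): neuron id, step within recorded window
    v_trace: np.ndarray  # (record_steps, N) float32, spikes capped at 30 mV
    S: np.ndarray  # (record_steps,) global mean membrane potential
    is_excitatory: np.ndarray
    config: SimulationConfig

    @property
    def rate_exc(self) -> float:
        return firing_rate(self)


def make_neuron_params(
    is_excitatory: np.ndarray, rng: np.random.Generator
) -> NeuronParams:
    """Draw per-neuron parameters from the excitatory/inhibitory repertoires."""
    is_exc = np.asarray(is_excitatory, dtype=bool)
    n = is_exc.size
    r = rng.random(n)
    a = np.where(is_exc, 0.02, 0.02 + 0.08 * r)
    b = np.where(is_exc, 0.2, 0.25 - 0.05 * r)
    c = np.where(is_exc, -65.0 + 15.0 * r, -65.0)
    d = np.where(is_exc, 8.0 - 6.0 * r, 2.0)
    i_scale = np.where(is_exc, 5.0, 2.0)
    return NeuronParams(a=a, b=b, c=c, d=d, i_scale=i_scale, r=r, is_excitatory=is_exc)


# -- single-step primitives (reference implementations) ---------------------


def derivatives(v, u, a, b, i_noise, s_in):
    """Right-hand side of the membrane/recovery equations (h-free)."""
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_noise + s_in
    du = a * (b * v - u)
    return dv, du


def apply_reset(v, u, c, d):
    """After-spike reset; returns (v', u', spiked)."""
    spiked = v >= SPIKE_THRESHOLD
    v_new = np.where(spiked, c, v)
    u_new = np.where(spiked, u + d, u)
    return v_new, u_new, spiked


def rk2_step(v, u, a, b, i_noise, s_in, h):
    """Midpoint RK-2 update with inputs held constant across the step."""
    dv1, du1 = derivatives(v, u, a, b, i_noise, s_in)
    vm = v + 0.5 * h * dv1
    um = u + 0.5 * h * du1
    dv2, du2 = derivatives(vm, um, a, b, i_noise, s_in)
    return v + h * dv2, u + h * du2


# -- integration kernel -----------------------------------------------------


@njit(cache=False)
def _integrate_kernel(
    v, u, a, b, c, d, noise, indptr, indices, sign, w, h, transient, record
):  # pragma: no cover - compiled; equivalence tested against the numpy path
    n = v.size
    total = transient + record
    v_trace = np.empty((record, n), dtype=np.float32)
    spikes = np.zeros((record, n), dtype=np.bool_)
    s_acc = np.zeros(n)
    s_next = np.zeros(n)
    for t in range(total):
        for i in range(n):
            s_in = w * s_acc[i]
            i_n = noise[t, i]
            vi = v[i]
            ui = u[i]
            dv1 = 0.04 * vi * vi + 5.0 * vi + 140.0 - ui + i_n + s_in
            du1 = a[i] * (b[i] * vi - ui)
            vm = vi + 0.5 * h * dv1
            um = ui + 0.5 * h * du1
            dv2 = 0.04 * vm * vm + 5.0 * vm + 140.0 - um + i_n + s_in
            du2 = a[i] * (b[i] * vm - um)
            vi = vi + h * dv2
            ui = ui + h * du2
            if not np.isfinite(vi):
                return v_trace, spikes, t
            if vi >= 30.0:
                if t >= transient:
                    v_trace[t - transient, i] = 30.0
                    spikes[t - transient, i] = True
                for e in range(indptr[i], indptr[i + 1]):
                    s_next[indices[e]] += sign[i]
                vi = c[i]
                ui = ui + d[i]
            else:
                if t >= transient:
                    v_trace[t - transient, i] = vi
            v[i] = vi
            u[i] = ui
        for i in range(n):
            s_acc[i] = s_next[i]
            s_next[i] = 0.0
    return v_trace, spikes, -1


def _integrate_numpy(v, u, a, b, c, d, noise, indptr, indices, sign, w, h, transient, record):
    """Vectorized reference path, identical semantics to the compiled kernel."""
    n = v.size
    total = transient + record
    v_trace = np.empty((record, n), dtype=np.float32)
    spikes = np.zeros((record, n), dtype=bool)
    s_acc = np.zeros(n)
    for t in range(total):
        s_in = w * s_acc
        v, u = rk2_step(v, u, a, b, noise[t], s_in, h)
        if not np.all(np.isfinite(v)):
            return v_trace, spikes, t
        fired = v >= SPIKE_THRESHOLD
        if t >= transient:
            v_trace[t - transient] = np.minimum(v, SPIKE_THRESHOLD).astype(np.float32)
            spikes[t - transient] = fired
        v, u, _ = apply_reset(v, u, c, d)
        s_acc = np.zeros(n)
        for i in np.flatnonzero(fired):
            np.add.at(s_acc, indices[indptr[i] : indptr[i + 1]], sign[i])
    return v_trace, spikes, -1


def _outgoing_csr(net: HierarchicalNetwork) -> tuple[np.ndarray, np.ndarray]:
    """CSR layout (indptr, indices) of outgoing links per source neuron."""
    order = np.argsort(net.edges[:, 0], kind="stable")
    src = net.edges[order, 0]
    indices = np.ascontiguousarray(net.edges[order, 1])
    indptr = np.searchsorted(src, np.arange(net.n_nodes + 1))
    return indptr.astype(np.int64), indices.astype(np.int64)


def simulate(
    net: HierarchicalNetwork,
    config: SimulationConfig,
    rng: np.random.Generator,
    use_numba: bool = _HAVE_NUMBA,
) -> SimulationResult:
    """Run the network simulation and record the post-transient window.

    Spikes emitted at step t deliver their signed synaptic kick to every
    outgoing neighbour at step t+1 only.  Thalamic noise is drawn
    independently per neuron per step and held constant within the RK-2
    step.  Stored membrane traces cap spikes at 30 mV, so S(t) is the mean
    of the capped traces.
    """
    is_exc = net.is_excitatory
    params = make_neuron_params(is_exc, rng)
    indptr, indices = _outgoing_csr(net)
    sign = np.where(is_exc, 1.0, -1.0)

    total = config.transient_steps + config.record_steps
    # mean drive + diffusion-consistent noise; see SimulationConfig
    noise = config.drive_mean * params.i_scale + rng.standard_normal(
        (total, net.n_nodes)
    ) * (config.noise_scale * params.i_scale / np.sqrt(config.h))

    v0 = np.full(net.n_nodes, -65.0)
    u0 = params.b * v0

    kernel = _integrate_kernel if use_numba and _HAVE_NUMBA else _integrate_numpy
    v_trace, spikes, err = kernel(
        v0.copy(), u0.copy(), params.a, params.b, params.c, params.d,
        noise, indptr, indices, sign,
        float(config.weight), float(config.h),
        int(config.transient_steps), int(config.record_steps),
    )
    if err >= 0:
        raise FloatingPointError(f"non-finite membrane potential at step {err}")

    steps, neurons = np.nonzero(spikes)
    raster = np.column_stack([neurons, steps]).astype(np.int64)
    S = v_trace.mean(axis=1, dtype=np.float64)
    return SimulationResult(
        raster=raster, v_trace=v_trace, S=S, is_excitatory=is_exc, config=config
    )


def firing_rate(result: SimulationResult, duration_s: "float | None" = None) -> float:
    """Mean excitatory firing rate in spikes per second per neuron."""
    if duration_s is None:
        duration_s = result.config.recorded_duration_s
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_exc = int(result.is_excitatory.sum())
    if n_exc == 0:
        return 0.0
    exc_spikes = int(result.is_excitatory[result.raster[:, 0]].sum()) if len(result.raster) else 0
    return exc_spikes / (n_exc * duration_s)


def calibrate_weight(
    net: HierarchicalNetwork,
    config: SimulationConfig,
    target_rate: float = 5.0,
    w_grid: "np.ndarray | None" = None,
    runs: int = 3,
    base_seed: int = 0,
) -> tuple[float, "list[tuple[float, float]]"]:
    """Smallest grid weight whose mean excitatory rate reaches ``target_rate``.

    Returns ``(w_star, curve)`` where ``curve`` is the full rate-vs-weight
    relation, each point averaged over ``runs`` independently seeded
    simulations.  Raises ``RuntimeError`` (with the curve attached) when
    the target is unreachable on the grid.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if w_grid is None:
        w_grid = np.arange(10.0, 70.0, 10.0) * (0.1 / config.h)
    curve = []
    for w in w_grid:
        cfg = dataclasses.replace(config, weight=float(w))
        rates = [
            firing_rate(simulate(net, cfg, np.random.default_rng([base_seed, j, int(w * 1000)])))
            for j in range(runs)
        ]
        curve.append((float(w), float(np.mean(rates))))
    for w, rate in curve:
        if rate >= target_rate:
            return w, curve
    err = RuntimeError(f"target rate {target_rate} spks/s unreachable on grid")
    err.curve = curve  # type: ignore[attr-defined]
    raise err
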