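"""Global lability of synchronization.

From 125 cluster-averaged membrane signals, instantaneous Hilbert phases
give pairwise phase differences; a pair counts as synchronized at step t
when |dtheta(t)| < pi/4 and its windowed synchronization index (mean
resultant length over nu = 50 forward steps) exceeds sqrt(1/2).  M(t) is
the number of synchronized pairs, and the lability

    ell(t) = |M(t+1) - M(t)|^2

measures how abruptly the synchronization pattern reorganizes: many small
values mean local rearrangements, heavy tails mean global
synchronization/desynchronization events.  Its density G(ell) ~ ell^-delta
is summarized by a bounded-support maximum-likelihood exponent, the
regime 0 < delta <= 1 where the density is normalizable only through its
cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import hilbert

from .dynamics import SimulationResult
from .network import HierarchicalNetwork

__all__ = [
    "LabilityResult",
    "cluster_signals",
    "analytic_phase",
    "phase_difference",
    "sync_index",
    "count_synchronized_pairs",
    "lability",
    "lability_density",
    "fit_powerlaw_delta",
    "lability_pipeline",
]

#: window length (steps) of the synchronization index
NU = 50
PHASE_TOL = np.pi / 4
GAMMA_MIN = np.sqrt(0.5)


@dataclass
class LabilityResult:
    M: np.ndarray  # synchronized-pair count per step
    ell: np.ndarray  # squared successive differences of M
    n_signals: int
    delta: "float | None" = None
    delta_mse: "float | None" = None
    support: "tuple[float, float] | None" = None


def cluster_signals(
    result: SimulationResult, net: HierarchicalNetwork, cluster_size: int = 5
) -> np.ndarray:
    """Mean membrane potential per 5-node cluster: (n_clusters, T) array."""
    if net.cluster5 is None:
        raise ValueError("network lacks cluster labels")
    labels = net.cluster5 if cluster_size == 5 else net.cluster25
    n_clusters = int(labels.max()) + 1
    v = result.v_trace  # (T, N)
    out = np.empty((n_clusters, v.shape[0]))
    for c in range(n_clusters):
        out[c] = v[:, labels == c].mean(axis=1, dtype=np.float64)
    return out


def analytic_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase from the discrete Hilbert transform.

    The signal is mean-removed first; a constant signal has no defined
    phase and raises.
    """
    signal = np.asarray(signal, dtype=float)
    x = signal - signal.mean()
    if np.allclose(x, 0.0):
        raise ValueError("constant signal: phase undefined")
    return np.angle(hilbert(x))


def _unit_phasors(signals: np.ndarray) -> np.ndarray:
    """exp(i*theta) per signal, via the analytic signal (rows = signals)."""
    x = signals - signals.mean(axis=1, keepdims=True)
    z = hilbert(x, axis=1)
    mag = np.abs(z)
    if np.any(mag == 0):
        raise ValueError("degenerate analytic signal")
    return (z / mag).astype(np.complex64)


def phase_difference(s_i: np.ndarray, s_j: np.ndarray) -> np.ndarray:
    """Wrapped instantaneous phase difference in (-pi, pi].

    Computed as the argument of the analytic signal of ``s_i`` times the
    conjugate of that of ``s_j``, which equals theta_i - theta_j wrapped.
    """
    if s_i.shape != s_j.shape:
        raise ValueError("signals must have equal length")
    p = _unit_phasors(np.vstack([s_i, s_j]))
    return np.angle(p[0] * np.conj(p[1]))


def sync_index(delta_theta: np.ndarray, nu: int = NU) -> np.ndarray:
    """Mean resultant length of the phase difference over [t, t+nu).

    1 means a constant phase lag during the whole window (full frequency
    locking), 0 a phase difference sweeping the circle.  The last ``nu``
    samples have no complete forward window and are dropped.
    """
    delta_theta = np.asarray(delta_theta)
    if delta_theta.size < nu:
        raise ValueError("window exceeds series length")
    ph = np.exp(1j * delta_theta)
    c = np.concatenate([[0.0 + 0.0j], np.cumsum(ph)])
    return np.abs(c[nu:] - c[:-nu]) / nu


def count_synchronized_pairs(
    signals: np.ndarray,
    nu: int = NU,
    edge_trim: "int | None" = None,
    pair_block: int = 512,
) -> np.ndarray:
    """Synchronized-pair count M(t) over all unordered signal pairs.

    A pair (i, j) is synchronized at t when |dtheta_ij(t)| < pi/4 and its
    synchronization index over [t, t+nu) exceeds sqrt(1/2).  The first and
    last ``edge_trim`` (default nu) samples are excluded to avoid the
    boundary distortion of the FFT-based analytic signal, and the final nu
    samples of the remainder are dropped with the incomplete windows.
    Pairs are processed in blocks to bound memory.
    """
    signals = np.asarray(signals, dtype=float)
    n, t_len = signals.shape
    if n < 2:
        raise ValueError("need at least two signals")
    if edge_trim is None:
        edge_trim = nu
    p = _unit_phasors(signals)[:, edge_trim : t_len - edge_trim]
    t_eff = p.shape[1] - nu
    if t_eff < 2:
        raise ValueError("series too short for the requested window")

    ii, jj = np.triu_indices(n, k=1)
    m = np.zeros(t_eff, dtype=np.int64)
    cos_tol = np.cos(PHASE_TOL)
    for start in range(0, ii.size, pair_block):
        bi = ii[start : start + pair_block]
        bj = jj[start : start + pair_block]
        q = p[bi] * np.conj(p[bj])  # exp(i * dtheta), (block, T')
        locked = q.real[:, :t_eff] > cos_tol
        c = np.cumsum(q, axis=1, dtype=np.complex128)
        c = np.concatenate([np.zeros((len(bi), 1), dtype=np.complex128), c], axis=1)
        gamma = np.abs(c[:, nu : nu + t_eff] - c[:, :t_eff]) / nu
        m += (locked & (gamma > GAMMA_MIN)).sum(axis=0)
    return m


def lability(m: np.ndarray) -> np.ndarray:
    """Squared change in the synchronized-pair count between steps."""
    m = np.asarray(m, dtype=np.int64)
    if m.size < 2:
        raise ValueError("M must have at least two samples")
    return np.diff(m) ** 2


def lability_density(
    ell_values: np.ndarray, n_bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Log-binned probability density of the positive lability values.

    Returns (bin centers, density).  Zero labilities — no change in the
    synchronization pattern — are excluded; the density integrates to one
    over the positive support.
    """
    ell = np.asarray(ell_values, dtype=float)
    pos = ell[ell > 0]
    if pos.size == 0:
        raise ValueError("no positive lability values")
    lo, hi = pos.min(), pos.max()
    if lo == hi:
        return np.array([lo]), np.array([1.0 / lo])
    bins = np.geomspace(lo * (1 - 1e-9), hi * (1 + 1e-9), n_bins + 1)
    counts, _ = np.histogram(pos, bins=bins)
    dens = counts / np.diff(bins) / pos.size
    centers = np.sqrt(bins[:-1] * bins[1:])
    keep = counts > 0
    return centers[keep], dens[keep]


def _log_norm(delta: float, lo: float, hi: float) -> float:
    """log of the normalization of x^-delta on [lo, hi]."""
    if abs(delta - 1.0) < 1e-9:
        return float(np.log(np.log(hi / lo)))
    p = 1.0 - delta
    return float(np.log((hi**p - lo**p) / p))


def fit_powerlaw_delta(
    ell_values: np.ndarray,
    ell_min: "float | None" = None,
    ell_max: "float | None" = None,
    min_samples: int = 100,
) -> tuple[float, float]:
    """Bounded-support ML estimate of delta in G(ell) ~ ell^-delta.

    Maximum likelihood for a power law with exponent in (0, 1] on the
    finite support [ell_min, ell_max] — the regime of shallow exponents
    where the density is normalizable only through its cutoffs.  Defaults:
    ell_min = 1, ell_max = 99th percentile of the positive values (guards
    against single extreme global events).  Returns ``(delta, mse)`` where
    mse is the mean squared log-residual of the log-binned density against
    the fitted line.
    """
    ell = np.asarray(ell_values, dtype=float)
    pos = ell[ell > 0]
    if ell_min is None:
        ell_min = 1.0
    if ell_max is None:
        ell_max = float(np.percentile(pos, 99)) if pos.size else 0.0
    x = pos[(pos >= ell_min) & (pos <= ell_max)]
    if x.size < min_samples:
        raise ValueError(
            f"only {x.size} samples in [{ell_min}, {ell_max}]; need {min_samples}"
        )
    mean_log = float(np.mean(np.log(x)))

    def nll(delta: float) -> float:
        return delta * mean_log + _log_norm(delta, ell_min, ell_max)

    res = minimize_scalar(nll, bounds=(1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(res.x)

    centers, dens = lability_density(x)
    model = centers**-delta / np.exp(_log_norm(delta, ell_min, ell_max))
    mse = float(np.mean((np.log10(dens) - np.log10(model)) ** 2))
    return delta, mse


def lability_pipeline(
    result: SimulationResult,
    net: HierarchicalNetwork,
    nu: int = NU,
    fit: bool = True,
) -> LabilityResult:
    """Cluster signals -> phases -> M(t) -> ell(t) -> density exponent.

    With a constant M (a fully locked or fully unlocked ensemble) the
    exponent is undefined and left as None rather than fitted.
    """
    sig = cluster_signals(result, net)
    m = count_synchronized_pairs(sig, nu=nu)
    ell = lability(m)
    out = LabilityResult(M=m, ell=ell, n_signals=sig.shape[0])
    if fit and np.any(ell > 0):
        try:
            pos = ell[ell > 0].astype(float)
            out.support = (1.0, float(np.percentile(pos, 99)))
            out.delta, out.delta_mse = fit_powerlaw_delta(ell)
        except ValueError:
            pass
    return out
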