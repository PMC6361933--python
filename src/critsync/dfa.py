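"""Detrended fluctuation analysis (DFA-1).

Quantifies long-range temporal correlation of a (possibly nonstationary)
series: the mean-subtracted series is integrated into a profile, the
profile is cut into non-overlapping windows of size n, a straight line is
fitted per window, and F(n) is the RMS of the pooled residuals.  A scaling
law F(n) ~ n^alpha defines the exponent: alpha = 0.5 for white noise,
1.0 for 1/f (pink) noise, 1.5 for Brownian noise.  The spectral slope of
the underlying signal, S(f) ~ 1/f^beta, relates to it as beta = 2*alpha - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = ["DFAResult", "dfa_profile", "dfa_fluctuation", "dfa_exponent"]


@dataclass
class DFAResult:
    n_values: np.ndarray
    F_values: np.ndarray
    alpha: float
    fit_range: tuple[int, int]
    fit_residual: float  # mean squared error of the log-log fit


def dfa_profile(series: np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-subtracted series."""
    series = np.asarray(series, dtype=float)
    if series.size < 16:
        raise ValueError("series too short for DFA")
    return np.cumsum(series - series.mean())


def dfa_fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS detrended fluctuation at window size n.

    Non-overlapping windows from the start of the profile; a trailing
    partial window is discarded.  Each window is detrended with its own
    ordinary-least-squares line.
    """
    profile = np.asarray(profile, dtype=float)
    if n < 4 or n > profile.size // 2:
        raise ValueError(f"window size {n} out of range for length {profile.size}")
    m = profile.size // n
    y = profile[: m * n].reshape(m, n)
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    slope = (y * xc).sum(axis=1) / denom
    resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * xc
    return float(np.sqrt(np.mean(resid**2)))


def dfa_exponent(
    series: np.ndarray,
    n_min: int = 10,
    n_max: "int | None" = None,
    n_points: int = 20,
) -> DFAResult:
    """Fit the DFA scaling exponent over log-spaced window sizes.

    alpha is the least-squares slope of log F(n) versus log n.  The
    default upper window is a quarter of the series length capped at 1000
    (a decade-spanning range for the standard 10^4-step recordings).
    Window sizes with F = 0 (exactly detrendable profiles) are excluded
    with a warning.
    """
    series = np.asarray(series, dtype=float)
    if n_max is None:
        n_max = min(1000, series.size // 4)
    if n_max > series.size // 4:
        raise ValueError("n_max exceeds a quarter of the series length")
    ns = np.unique(np.geomspace(n_min, n_max, n_points).round().astype(int))
    profile = dfa_profile(series)
    F = np.array([dfa_fluctuation(profile, int(n)) for n in ns])
    good = F > 0
    if not np.all(good):
        warnings.warn("zero fluctuation at some window sizes; excluded from fit")
    if good.sum() < 2:
        raise ValueError("not enough nonzero fluctuation values to fit")
    coef, res, *_ = np.polyfit(np.log(ns[good]), np.log(F[good]), 1, full=True)
    mse = float(res[0] / good.sum()) if len(res) else 0.0
    return DFAResult(
        n_values=ns,
        F_values=F,
        alpha=float(coef[0]),
        fit_range=(int(n_min), int(n_max)),
        fit_residual=mse,
    )
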