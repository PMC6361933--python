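"""Synthetic signal generators used as analysis oracles.

Colored-noise surrogates with a prescribed power-spectral slope beta
(S(f) ~ 1/f^beta, hence DFA exponent alpha = (beta + 1) / 2), sinusoid
ensembles with controlled phase offsets for the synchrony pipeline, and
bounded power-law samplers for the lability-exponent fit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "colored_noise",
    "white_noise",
    "brownian_noise",
    "sinusoid_ensemble",
    "powerlaw_samples",
]


def colored_noise(beta: float, length: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum S(f) ~ 1/f^beta, unit variance.

    Spectral synthesis: independent Gaussian Fourier coefficients shaped
    by f^(-beta/2), inverse real FFT, then standardization.  beta=0 is
    white noise (DFA alpha 0.5), beta=1 pink (alpha 1.0), beta=2
    Brownian-like (alpha 1.5).
    """
    if not 0.0 <= beta <= 3.0:
        raise ValueError(f"beta out of range: {beta}")
    if length < 256:
        raise ValueError("length must be >= 256")
    f = np.fft.rfftfreq(length)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    coefs = amp * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    x = np.fft.irfft(coefs, n=length)
    return (x - x.mean()) / x.std()


def white_noise(length: int, rng: np.random.Generator) -> np.ndarray:
    """Standard Gaussian white noise."""
    return rng.standard_normal(length)


def brownian_noise(length: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative sum of Gaussian white noise (random walk)."""
    return np.cumsum(rng.standard_normal(length))


def sinusoid_ensemble(
    n_signals: int,
    length: int,
    freq: float,
    phase_offsets: "np.ndarray | float" = 0.0,
    noise_std: float = 0.0,
    rng: "np.random.Generator | None" = None,
) -> np.ndarray:
    """Common-frequency sinusoids with per-signal phase offsets.

    ``freq`` is in cycles per sample.  Returns an (n_signals, length)
    array; additive Gaussian noise of std ``noise_std`` is applied per
    signal when requested.
    """
    offsets = np.broadcast_to(np.asarray(phase_offsets, dtype=float), (n_signals,))
    t = np.arange(length)
    x = np.sin(2.0 * np.pi * freq * t[None, :] + offsets[:, None])
    if noise_std > 0.0:
        if rng is None:
            raise ValueError("noise_std > 0 requires an rng")
        x = x + noise_std * rng.standard_normal(x.shape)
    return x


def powerlaw_samples(
    delta: float,
    n: int,
    support: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF samples from a density ~ x^-delta on [x_min, x_max].

    Valid for 0 < delta <= 1 (the bounded-support regime where the
    density is not normalizable without an upper cutoff).
    """
    x_min, x_max = support
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    if not 0.0 < x_min < x_max:
        raise ValueError("invalid support")
    u = rng.random(n)
    p = 1.0 - delta
    if abs(p) < 1e-12:  # log-uniform limit
        return x_min * (x_max / x_min) ** u
    # stable for delta near 1: work with expm1/log1p of p*log(x)
    a = np.expm1(p * np.log(x_min))
    b = np.expm1(p * np.log(x_max))
    return np.exp(np.log1p(a + u * (b - a)) / p)
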