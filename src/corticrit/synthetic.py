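"""Synthetic series with known exponents, used as estimator ground truth.

Every estimator in the toolkit (cutoff fit, power-law MLE, spectrum, DFA,
autocorrelation) is validated against samples whose true exponents are
known in closed form: sharply truncated discrete power laws, AR(1) noise
with characteristic time -1/ln(phi), and fractional Gaussian noise with a
prescribed Hurst exponent (circulant-embedding synthesis).
"""

from __future__ import annotations

import numpy as np

from .avalanches import sample_discrete_powerlaw

__all__ = ["sample_discrete_powerlaw", "ar1", "fractional_gaussian_noise"]


def ar1(n: int, phi: float, rng: np.random.Generator, sigma: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + eps; its autocorrelation
    is phi^lag, i.e. a pure exponential with tau = -1/ln(phi)."""
    if not (0 <= phi < 1):
        raise ValueError("need 0 <= phi < 1")
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def fractional_gaussian_noise(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample of length n with Hurst exponent H (Davies-Harte).

    The DFA exponent of fGn equals H; integrating it gives fBm with DFA
    exponent H + 1.
    """
    if not (0 < H < 1):
        raise ValueError("need 0 < H < 1")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise RuntimeError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    z = rng.normal(size=m) + 1j * rng.normal(size=m)
    w = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    return w[:n].real
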