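"""Discrete fractional Gaussian noise (FGN) generation.

FGN is the stationary increment process of fractional Brownian motion.
A single component with Hurst index ``H`` and per-step variance ``sigma**2``
has the autocovariance

    gamma(n) = (sigma**2 / 2) * (|n+1|**(2H) - 2|n|**(2H) + |n-1|**(2H)),

which decays as a power law for H != 0.5 (long-range positive correlations
for H > 0.5, anti-correlations for H < 0.5) and vanishes at all non-zero
lags for H = 0.5 (ordinary Brownian increments).

Two generators are provided. :func:`generate_fgn_fourier` filters a real
white-noise sequence by the square root of the FGN spectral density
(Fourier-filtering method); :func:`generate_fgn_exact` is an independent
circulant-embedding (Davies-Harte) construction used as a cross-check.
Both are exact up to the circular wrap-around of the covariance sequence,
which is made negligible by embedding the target length in a grid at least
twice as long.

Fiber trajectories need whole increment sequences up front: FGN is
non-Markovian, so a walk cannot be extended step by step without the full
correlation history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseParams",
    "IncrementSeries",
    "fgn_covariance",
    "generate_fgn_fourier",
    "generate_fgn_exact",
    "generate_increments_3d",
]


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of one FGN component.

    Parameters
    ----------
    hurst : float
        Hurst index, strictly between 0 and 1.  The simulator default is
        0.8 (superdiffusive, persistent increments).
    sigma : float
        Root-mean-square step per Cartesian component, in grid units
        (one grid unit = 6.6 um of tissue; the default 0.4 corresponds
        to 2.6 um).
    length : int
        Number of steps (increments) to generate.
    seed : int
        Non-negative seed; generation is deterministic given the seed.
    """

    hurst: float
    sigma: float = 0.4
    length: int = 2**18
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")


@dataclass(frozen=True)
class IncrementSeries:
    """Three statistically independent FGN components (x, y, z)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.x, self.y, self.z)

    def as_array(self) -> np.ndarray:
        """Stack into an (length, 3) float array of step vectors."""
        return np.stack([self.x, self.y, self.z], axis=1)

    def __len__(self) -> int:
        return len(self.x)


def fgn_covariance(lag, hurst: float, sigma2: float):
    """Closed-form FGN autocovariance at non-negative integer lag(s).

    gamma(n) = (sigma2 / 2) * (|n+1|^(2H) - 2 |n|^(2H) + |n-1|^(2H))

    ``lag`` may be a scalar or array; the covariance is an even function
    of the lag, so only non-negative lags are accepted.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if not sigma2 > 0.0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    n = np.asarray(lag, dtype=float)
    if np.any(n < 0):
        raise ValueError("lag must be non-negative")
    h2 = 2.0 * hurst
    out = 0.5 * sigma2 * (
        np.abs(n + 1.0) ** h2 - 2.0 * np.abs(n) ** h2 + np.abs(n - 1.0) ** h2
    )
    if np.isscalar(lag) or np.ndim(lag) == 0:
        return float(out)
    return out


def _circular_covariance(length: int, hurst: float, sigma2: float) -> np.ndarray:
    """Even circular extension of the covariance on a grid of 2*length."""
    m = 2 * length
    lags = np.minimum(np.arange(m), m - np.arange(m))
    return fgn_covariance(lags, hurst, sigma2)


def _spectral_density(length: int, hurst: float, sigma2: float) -> np.ndarray:
    """Eigenvalues of the circulant embedding = discrete spectral density.

    For FGN with 0 < H < 1 these are non-negative; tiny negative values
    from floating-point round-off are clipped.
    """
    lam = np.fft.fft(_circular_covariance(length, hurst, sigma2)).real
    if lam.min() < -1e-8 * lam.max():
        raise AssertionError(
            "circulant embedding of the FGN covariance is not positive "
            f"semi-definite (min eigenvalue {lam.min():g})"
        )
    return np.clip(lam, 0.0, None)


def generate_fgn_fourier(params: NoiseParams) -> np.ndarray:
    """Generate one FGN component by Fourier filtering.

    White Gaussian noise of length 2L is filtered in the frequency domain
    by the square root of the FGN spectral density (the DFT of the circular
    covariance sequence); the first L values are returned.  The output is
    a stationary mean-zero Gaussian sequence whose autocovariance matches
    :func:`fgn_covariance` at every lag below L.
    """
    if params.length < 2:
        raise ValueError("Fourier filtering needs length >= 2")
    rng = np.random.default_rng(params.seed)
    m = 2 * params.length
    sqrt_s = np.sqrt(_spectral_density(params.length, params.hurst, params.sigma**2))
    white = rng.standard_normal(m)
    filtered = np.fft.ifft(np.fft.fft(white) * sqrt_s).real
    return filtered[: params.length]


def generate_fgn_exact(params: NoiseParams) -> np.ndarray:
    """Generate one FGN component by circulant embedding (Davies-Harte).

    Independent Gaussian Fourier coefficients with variances equal to the
    circulant eigenvalues are assembled with Hermitian symmetry and
    transformed back; the covariance of the result equals the circular
    covariance exactly, hence :func:`fgn_covariance` at lags < length.
    Serves as the independent oracle for the Fourier-filtering generator.
    """
    if params.length < 2:
        raise ValueError("circulant embedding needs length >= 2")
    rng = np.random.default_rng(params.seed)
    m = 2 * params.length
    lam = _spectral_density(params.length, params.hurst, params.sigma**2)
    half = m // 2
    coef = np.empty(m, dtype=complex)
    coef[0] = np.sqrt(lam[0]) * rng.standard_normal()
    coef[half] = np.sqrt(lam[half]) * rng.standard_normal()
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    interior = np.sqrt(lam[1:half] / 2.0) * (a + 1j * b)
    coef[1:half] = interior
    coef[half + 1 :] = np.conj(interior[::-1])
    series = np.sqrt(m) * np.fft.ifft(coef).real
    return series[: params.length]


def _component_seed(seed: int, component: int, fiber: int | None = None) -> np.random.SeedSequence:
    key = (component,) if fiber is None else (fiber, component)
    return np.random.SeedSequence(entropy=seed, spawn_key=key)


def generate_increments_3d(
    params: NoiseParams,
    generator=generate_fgn_fourier,
    fiber_index: int | None = None,
) -> IncrementSeries:
    """Generate the three independent step components of one fiber.

    Each Cartesian component comes from its own seeded stream, derived
    deterministically from ``params.seed`` and the component index (and,
    for cohort runs, the fiber index), so results do not depend on
    generation order or parallel scheduling.
    """
    comps = []
    for axis in range(3):
        ss = _component_seed(params.seed, axis, fiber_index)
        # re-wrap: generators take integer seeds for a stable public contract
        sub_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        comps.append(
            generator(
                NoiseParams(params.hurst, params.sigma, params.length, sub_seed)
            )
        )
    return IncrementSeries(*comps)
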