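"""Multi-exposure speckle contrast from Doppler spectra, plus noise.

The electric-field autocorrelation follows from the Doppler spectrum by the
Wiener–Khinchine theorem, g¹(τ) = |F⁻¹{H(f)}|, and the contrast at exposure
time T from the time-integrated speckle statistics

    K²(T) = (2β/T) ∫₀ᵀ |g¹(τ)|² (1 − τ/T) dτ,

with coherence factor β (β = 1 for a calibrated system where a static
target gives K = 1).  Measurement noise is a random-walk sequence of
contrast offsets across the exposure ladder, scaled by the average contrast
over all exposures.  The classic single-exposure perfusion estimate
P_SE(T) = 1/K(T) − 1 is included as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .config import ContrastConfig
from .doppler_spectrum import DopplerHistogram

__all__ = [
    "EXPOSURES_MS",
    "MultiExposureContrast",
    "NoiseParams",
    "autocorrelation_from_histogram",
    "contrast_from_autocorrelation",
    "contrast_curve_from_histogram",
    "make_tau_grid",
    "add_contrast_noise",
    "single_exposure_perfusion",
]

#: the seven canonical exposure times, ms
EXPOSURES_MS = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])


@dataclass
class MultiExposureContrast:
    """K(T) at the seven canonical exposures (noise-free or noisy)."""

    K: np.ndarray
    exposures_ms: np.ndarray = field(default_factory=lambda: EXPOSURES_MS.copy())

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.exposures_ms = np.asarray(self.exposures_ms, dtype=float)
        if self.K.shape != self.exposures_ms.shape:
            raise ValueError("K and exposures must align")

    @property
    def K2(self) -> np.ndarray:
        """Squared contrast — the network input vector."""
        return self.K**2


@dataclass
class NoiseParams:
    """Constants of the contrast-noise random walk (speckle-sampling noise)."""

    eta_1: float = 0.02
    eta_diff: np.ndarray = field(default_factory=lambda: np.full(6, 0.01))
    contrast_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.eta_diff = np.asarray(self.eta_diff, dtype=float)
        if self.eta_1 <= 0 or np.any(self.eta_diff <= 0):
            raise ValueError("noise constants must be positive")
        if self.eta_diff.size != 6:
            raise ValueError("eta_diff covers T = 2,4,8,16,32,64 ms")

    @classmethod
    def from_config(cls, cfg: ContrastConfig) -> "NoiseParams":
        return cls(cfg.eta_1, np.asarray(cfg.eta_diff), cfg.contrast_floor)


def autocorrelation_from_histogram(H: DopplerHistogram, tau_s) -> np.ndarray:
    """|g¹(τ)| = |F⁻¹{H}| on the given τ grid (seconds).

    The inverse transform of the symmetric two-sided extension reduces to a
    cosine sum over the one-sided histogram; |g¹(0)| = 1 for normalized H.
    """
    return H.normalized().g1(np.asarray(tau_s, dtype=float))


def make_tau_grid(T_s: float, n: int = 2048, span: float = 1e-8) -> np.ndarray:
    """Log-spaced quadrature nodes on (span·T, T] for one exposure."""
    if T_s <= 0:
        raise ValueError("exposure time must be positive")
    return np.geomspace(span * T_s, T_s, n)


def contrast_from_autocorrelation(g1, tau_s, T_s: float, beta: float = 1.0) -> float:
    """K(T) by composite quadrature of the time-integrated-speckle integral.

    ``g1`` are |g¹| values on ``tau_s`` (need not extend past T; nodes above
    T are ignored).  Simpson quadrature on the log-dense grid, with the
    [0, τ_min] head handled as |g¹| ≈ |g¹(τ_min)| (exact to O(τ_min)).
    """
    if T_s <= 0:
        raise ValueError("exposure time must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    g1 = np.asarray(g1, dtype=float)
    tau = np.asarray(tau_s, dtype=float)
    keep = tau <= T_s * (1.0 + 1e-12)
    tau, g1 = tau[keep], g1[keep]
    if tau.size < 3:
        raise ValueError("tau grid too coarse for quadrature")
    integrand = g1**2 * (1.0 - tau / T_s)
    integral = simpson(integrand, x=tau)
    # head segment [0, tau[0]]: integrand smooth, value ≈ g1(tau0)^2
    integral += tau[0] * g1[0] ** 2 * (1.0 - 0.5 * tau[0] / T_s)
    k2 = 2.0 * beta / T_s * integral
    return float(np.sqrt(max(k2, 0.0)))


def contrast_curve_from_histogram(H: DopplerHistogram,
                                  cfg: ContrastConfig | None = None) -> MultiExposureContrast:
    """Noise-free K(T) at the seven canonical exposures from H(f)."""
    cfg = cfg or ContrastConfig()
    Ks = []
    for T_ms in cfg.exposures_ms:
        T = T_ms * 1e-3
        tau = make_tau_grid(T, cfg.n_tau, cfg.tau_span)
        g1 = autocorrelation_from_histogram(H, tau)
        Ks.append(contrast_from_autocorrelation(g1, tau, T, cfg.beta))
    return MultiExposureContrast(np.array(Ks), np.asarray(cfg.exposures_ms))


def add_contrast_noise(contrast: MultiExposureContrast, params: NoiseParams,
                       rng: np.random.Generator) -> MultiExposureContrast:
    """Add the exposure-correlated contrast noise random walk.

    K_noise(1 ms) = ⟨K⟩ ξ₁ η₁ and K_noise(T) = K_noise(T/2) + ⟨K⟩ ξ_T
    η_diff(T) for the doubling ladder, ξ i.i.d. standard normal; the noisy
    contrast is clipped at a small positive floor.
    """
    noisy = noisy_contrast_batch(contrast.K[None, :], params, rng)[0]
    return MultiExposureContrast(noisy, contrast.exposures_ms.copy())


def noisy_contrast_batch(K: np.ndarray, params: NoiseParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Vectorized noise walk over a (N, 7) batch of contrast curves."""
    K = np.asarray(K, dtype=float)
    mean_K = K.mean(axis=1, keepdims=True)
    xi = rng.standard_normal(K.shape)
    eta = np.concatenate([[params.eta_1], params.eta_diff])
    noise = np.cumsum(mean_K * xi * eta, axis=1)
    return np.maximum(K + noise, params.contrast_floor)


def single_exposure_perfusion(K) -> np.ndarray | float:
    """P_SE = 1/K − 1, the inverse-contrast perfusion estimate (arbitrary
    units); K = 1 (static) gives 0."""
    K_arr = np.asarray(K, dtype=float)
    if np.any(K_arr <= 0):
        raise ValueError("contrast must be positive")
    out = 1.0 / K_arr - 1.0
    return float(out) if np.isscalar(K) else out
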