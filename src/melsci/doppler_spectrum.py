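"""Optical Doppler power spectra for the layered skin model.

A photon scattered once by a moving RBC picks up a Doppler frequency

    f = |q| v |cos ψ| / 2π,   |q| = 2 k sin(θ/2),   k = 2π n_tissue / λ0,

with θ drawn from the Gegenbauer-kernel phase function and ψ (angle between
the scattering vector and the RBC velocity) uniform on the sphere, so
cos ψ ~ U(−1, 1).  Light shifted n times carries the n-fold
(cross-)correlation of the single-shift spectrum; the number of shifts a
photon experiences in a dermis layer follows a compound Poisson law —
Poisson vessel passages, each contributing a Poisson number of scattering
events along the mean chord — which over-disperses the counts relative to
homogeneously distributed blood (the vessel-packaging effect on shift
statistics).  The final spectrum H(f) mixes all of this over the speed
distribution, the per-layer path lengths, and the shift counts.

The biological-zero residual observed during full occlusion is modeled as
an empirical exponential spectral density 10^(ξ_offset + f ξ_slope) added to
H(f) for f > 0.

Two equivalent evaluation routes are provided:

* an explicit gridded route building H(f) (this module's public surface),
* a τ-domain route (`TauBasis`) evaluating the field autocorrelation
  directly through shift-count probability generating functions, used by the
  bulk dataset pipeline; for a shift-count pgf G and single-shift
  autocorrelation ĝ1(τ) = Σ_f H1(f) cos(2πfτ), the composed autocorrelation
  is exactly Σ_n P(n) ĝ1^n = G(ĝ1(τ)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.special import gammaln, roots_legendre, sici

from .config import DopplerConfig
from .photon_mc import JointPathDistribution
from .skin_model import SkinModelParams, SpeedDistribution

__all__ = [
    "DopplerHistogram",
    "ShiftCountDistribution",
    "GridOverflowError",
    "gegenbauer_anisotropy",
    "gegenbauer_mu_nodes",
    "single_shift_histogram",
    "single_shift_histogram_uniform",
    "n_shift_histogram",
    "shift_count_distribution",
    "layer_shift_rates",
    "compose_doppler_histogram",
    "add_biological_zero",
    "biological_zero_bin_mass",
    "biological_zero_g1",
    "TauBasis",
]


class GridOverflowError(ValueError):
    """Spectral mass beyond the frequency grid exceeded tolerance."""

    def __init__(self, msg: str, required_f_max: float):
        super().__init__(msg)
        self.required_f_max = required_f_max


# --------------------------------------------------------------------------
# Gegenbauer kernel phase function


def _gk_check(g: float, alpha: float) -> None:
    if not (0.0 < g < 1.0) or alpha <= -0.5:
        raise ValueError("Gegenbauer kernel requires 0 < g < 1, alpha > -1/2")


def _gk_ppf(u, g: float, alpha: float):
    """Inverse CDF of mu = cos(theta); analytic for alpha != 0."""
    if abs(alpha) < 1e-12:
        # limiting log form
        lo, hi = np.log(1.0 + g), np.log(1.0 - g)
        t = lo + np.asarray(u) * (hi - lo)
        return (1.0 + g * g - np.exp(2.0 * t)) / (2.0 * g)
    lo = (1.0 + g) ** (-2.0 * alpha)
    hi = (1.0 - g) ** (-2.0 * alpha)
    t = lo + np.asarray(u) * (hi - lo)
    return (1.0 + g * g - t ** (-1.0 / alpha)) / (2.0 * g)


def gegenbauer_anisotropy(g: float, alpha: float, n_quad: int = 512) -> float:
    """Mean cosine ⟨cos θ⟩ of the normalized Gegenbauer kernel, by quadrature.

    Gauss–Legendre in the CDF variable (equal-probability parameterization),
    which handles the sharp forward peak of strongly anisotropic kernels.
    """
    _gk_check(g, alpha)
    x, w = roots_legendre(n_quad)
    u = 0.5 * (x + 1.0)
    return float(np.sum(0.5 * w * _gk_ppf(u, g, alpha)))


def gegenbauer_mu_nodes(g: float, alpha: float, n: int) -> np.ndarray:
    """n equal-probability cos(theta) nodes (each of weight 1/n)."""
    _gk_check(g, alpha)
    u = (np.arange(n) + 0.5) / n
    return _gk_ppf(u, g, alpha)


# --------------------------------------------------------------------------
# Doppler histograms


@dataclass
class DopplerHistogram:
    """One-sided Doppler power spectrum on a uniform frequency grid.

    ``power[j]`` is the probability mass in the cell centered at ``freq[j]``;
    the f = 0 cell carries the unshifted (heterodyne) delta.  Σ power = 1.
    """

    freq: np.ndarray  # Hz, uniform, freq[0] == 0
    power: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freq[1] - self.freq[0])

    @property
    def zero_shift_weight(self) -> float:
        return float(self.power[0])

    def normalized(self) -> "DopplerHistogram":
        return DopplerHistogram(self.freq, self.power / self.power.sum())

    def g1(self, tau) -> np.ndarray:
        """|g¹(τ)| via the Wiener–Khinchine theorem (cosine sum over the
        symmetric two-sided extension)."""
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        out = np.empty_like(tau)
        # chunk to bound memory for long tau grids
        for a in range(0, tau.size, 512):
            t = tau[a:a + 512]
            out[a:a + 512] = np.abs(
                np.cos(2.0 * np.pi * np.outer(t, self.freq)) @ self.power)
        return out


def _grid(cfg: DopplerConfig) -> np.ndarray:
    return np.linspace(0.0, cfg.f_max_hz, cfg.n_freq)


def _k_over_pi(cfg: DopplerConfig) -> float:
    # (k/π) with k = 2π n / λ0, in 1/mm so that f [Hz] = (k/π) sin(θ/2) v[mm/s] Z
    lam_mm = cfg.wavelength_nm * 1e-6
    return 2.0 * cfg.n_tissue / lam_mm


def _edge_cdf_to_hist(cdf_at_edges: np.ndarray) -> np.ndarray:
    return np.diff(cdf_at_edges)


def _cell_edges(freq: np.ndarray) -> np.ndarray:
    df = freq[1] - freq[0]
    return np.concatenate([[0.0], freq[:-1] + df / 2.0, [freq[-1] + df / 2.0]])


def _check_overflow(overflow: float, f_req: float, cfg: DopplerConfig) -> None:
    if overflow > cfg.overflow_tol:
        raise GridOverflowError(
            f"spectral mass {overflow:.3e} beyond the grid exceeds "
            f"tolerance {cfg.overflow_tol}; a grid to f_max >= {f_req:.3e} Hz "
            "is required", f_req)


def _single_shift_raw(v: float, cfg: DopplerConfig,
                      uniform: bool) -> tuple[np.ndarray, float, float]:
    """(power with out-of-grid residual folded into the last cell,
    overflow mass, largest attainable frequency)."""
    freq = _grid(cfg)
    if v < 0:
        raise ValueError("speed must be nonnegative")
    power = np.zeros(cfg.n_freq)
    if v == 0.0:
        power[0] = 1.0
        return power, 0.0, 0.0

    mu = gegenbauer_mu_nodes(cfg.gk_g, cfg.gk_alpha, cfg.n_theta)
    sin_half = np.sqrt(np.maximum(0.0, (1.0 - mu) / 2.0))
    fm = _k_over_pi(cfg) * sin_half * v  # per-theta max frequency
    fm = np.maximum(fm, 1e-300)
    edges = _cell_edges(freq)

    cdf = np.zeros(edges.size)
    for a in range(0, fm.size, 256):  # chunked mean over theta nodes
        z = np.minimum(edges[None, :] / fm[a:a + 256, None], 1.0)
        if uniform:
            # speed ~ U(0, v): f = fm * Z with Z = U·|cosψ|, F_Z(z) = z(1−ln z)
            with np.errstate(divide="ignore", invalid="ignore"):
                Fz = np.where(z > 0, z * (1.0 - np.log(np.maximum(z, 1e-300))), 0.0)
            Fz = np.minimum(Fz, 1.0)
        else:
            Fz = z  # point speed: f = fm |cosψ|, uniform CDF
        cdf += Fz.sum(axis=0)
    cdf /= fm.size

    power = _edge_cdf_to_hist(cdf)
    overflow = 1.0 - cdf[-1]
    power[-1] += overflow  # fold the residual; callers police the tolerance
    return power, float(overflow), float(fm.max())


def _single_shift(v: float, cfg: DopplerConfig, uniform: bool) -> DopplerHistogram:
    power, overflow, f_req = _single_shift_raw(v, cfg, uniform)
    _check_overflow(overflow, f_req, cfg)
    return DopplerHistogram(_grid(cfg), power)


def single_shift_histogram(v: float, cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Doppler spectrum of light shifted once by RBCs moving at speed v (mm/s).

    Deterministic quadrature over the Gegenbauer scattering angle and the
    uniform RBC direction; mass is zero above f_max = 2 n_tissue v / λ0.
    """
    return _single_shift(v, cfg or DopplerConfig(), uniform=False)


def single_shift_histogram_uniform(top_speed: float,
                                   cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Single-shift spectrum for one parabolic-flow component: speeds uniform
    on [0, top_speed]."""
    return _single_shift(top_speed, cfg or DopplerConfig(), uniform=True)


def _two_sided_wrapped(power: np.ndarray, pad: int) -> np.ndarray:
    """Symmetric two-sided extension in wrap-around (FFT) layout."""
    n = power.size
    ts = np.zeros(pad)
    ts[0] = power[0]
    ts[1:n] = power[1:] / 2.0
    ts[pad - n + 1:] = power[1:][::-1] / 2.0
    return ts


def n_shift_histogram(single: DopplerHistogram, n: int,
                      cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Spectrum of light Doppler shifted n times: the (n−1)-fold
    cross-correlation of the single-shift spectrum with itself.

    Doppler spectra are symmetric, so cross-correlation equals convolution
    on the two-sided extension; computed exactly by zero-padded FFT, folded
    back to one-sided.  Mass pushed beyond the grid is checked against the
    overflow tolerance and then renormalized away.
    """
    cfg = cfg or DopplerConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return DopplerHistogram(single.freq.copy(), single.power.copy())
    nf = single.power.size
    m = 2 * nf - 1
    pad = next_fast_len(n * (m - 1) + 1)  # exact linear n-fold convolution
    ts = _two_sided_wrapped(single.power, pad)
    res = irfft(rfft(ts) ** n, pad)
    res = np.maximum(res, 0.0)
    # fold ±f and measure what lies beyond the grid
    out = np.empty(nf)
    out[0] = res[0]
    out[1:] = res[1:nf] + res[pad - 1:pad - nf:-1]
    inside = out.sum()
    _check_overflow(1.0 - inside, n * float(single.freq[-1]), cfg)
    return DopplerHistogram(single.freq.copy(), out / inside)


# --------------------------------------------------------------------------
# Shift counts


@dataclass
class ShiftCountDistribution:
    """P(n) of the number of Doppler-shifting events of a detected photon."""

    probs: np.ndarray  # over n = 0 .. n_cap; sums to 1

    @property
    def mean(self) -> float:
        return float(np.sum(np.arange(self.probs.size) * self.probs))

    @property
    def variance(self) -> float:
        n = np.arange(self.probs.size)
        return float(np.sum(n * n * self.probs) - self.mean**2)


def layer_shift_rates(c_blood: float, d_vessels: float,
                      mus_blood: float) -> tuple[float, float]:
    """(vessel-passage rate per mm, mean shifts per passage).

    Blood confined to cylinders of diameter d: a photon crosses vessels at
    rate c / d_chord per unit path (c = RBC tissue fraction, d_chord =
    π d / 4 the mean chord of a cylinder) and each passage scatters
    Poisson(μs,blood · d_chord) times, so the mean shift count per unit path
    is the homogeneous value c μs,blood while the variance is inflated by
    (1 + μs,blood d_chord).
    """
    if c_blood < 0 or d_vessels <= 0 or mus_blood <= 0:
        raise ValueError("invalid blood parameters")
    d_chord = np.pi * d_vessels / 4.0
    c = c_blood / 100.0
    return c / d_chord, mus_blood * d_chord


def _compound_poisson_probs(lam_p: np.ndarray, m: float, n_cap: int) -> np.ndarray:
    """P(n), n = 0..n_cap, of a Poisson(lam_p)-fold sum of Poisson(m) counts,
    for an array of passage means lam_p (rows)."""
    lam_p = np.atleast_1d(lam_p)
    p_max = int(np.ceil(lam_p.max() + 10.0 * np.sqrt(lam_p.max() + 1.0) + 20))
    p = np.arange(p_max + 1)
    # Poisson(p; lam) for each lam row
    logp = p[None, :] * np.log(np.maximum(lam_p[:, None], 1e-300)) \
        - lam_p[:, None] - gammaln(p[None, :] + 1.0)
    w_pass = np.exp(logp)
    w_pass[lam_p == 0.0] = 0.0
    w_pass[lam_p == 0.0, 0] = 1.0
    # Poisson(n; p*m)
    n = np.arange(n_cap + 1)
    pm = np.maximum(p[:, None] * m, 1e-300)
    logn = n[None, :] * np.log(pm) - p[:, None] * m - gammaln(n[None, :] + 1.0)
    pois_n = np.exp(logn)
    pois_n[0] = 0.0
    pois_n[0, 0] = 1.0
    return w_pass @ pois_n  # (n_l, n_cap+1)


def shift_count_distribution(path_lengths, path_weights, c_blood: float,
                             d_vessels: float, mus_blood: float = 222.0,
                             cfg: DopplerConfig | None = None) -> ShiftCountDistribution:
    """Shift-count distribution marginalized over a layer's path lengths.

    Compound Poisson per path length l — passages ~ Poisson(l c / d_chord),
    shifts per passage ~ Poisson(μs,blood d_chord) — mixed over the
    (normalized) path-length weights.  Truncated at the smallest n with
    cumulative probability > 1 − shift_tail_eps (capped at n_max), residual
    mass assigned to the cap.
    """
    cfg = cfg or DopplerConfig()
    l = np.asarray(path_lengths, dtype=float)
    w = np.asarray(path_weights, dtype=float)
    w = w / w.sum()
    rate, m = layer_shift_rates(c_blood, d_vessels, mus_blood)
    probs = w @ _compound_poisson_probs(l * rate, m, cfg.n_max)
    csum = np.cumsum(probs)
    above = np.nonzero(csum > 1.0 - cfg.shift_tail_eps)[0]
    keep = int(above[0]) if above.size else cfg.n_max
    out = probs[: keep + 1].copy()
    out[keep] += max(0.0, 1.0 - csum[keep])  # residual tail mass to the cap
    return ShiftCountDistribution(out / out.sum())


# --------------------------------------------------------------------------
# Composition


_H1_CACHE: dict = {}


def _h1_components(top_speeds: tuple, cfg: DopplerConfig) -> tuple:
    """Cached (spectra, overflow masses, max frequencies) of the uniform
    mixture components; overflow is policed at the mixture level so unused
    fast components cannot poison a slow model."""
    key = (top_speeds, cfg.f_max_hz, cfg.n_freq, cfg.n_theta, cfg.gk_g,
           cfg.gk_alpha, cfg.wavelength_nm, cfg.n_tissue)
    if key not in _H1_CACHE:
        rows = [_single_shift_raw(s, cfg, uniform=True) for s in top_speeds]
        _H1_CACHE[key] = (np.stack([r[0] for r in rows]),
                          np.array([r[1] for r in rows]),
                          np.array([r[2] for r in rows]))
    return _H1_CACHE[key]


def mixture_single_shift(speed_dist: SpeedDistribution,
                         cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Single-shift spectrum marginalized over the RBC speed distribution.

    The probability that a shift comes from speed v is proportional to the
    RBC concentration c_RBC(v) (scattering probability tracks RBC number
    density, not velocity), i.e. the mixture weights themselves.
    """
    cfg = cfg or DopplerConfig()
    comps, overflow, f_req = _h1_components(tuple(speed_dist.top_speeds), cfg)
    w = speed_dist.weights
    _check_overflow(float(w @ overflow), float(f_req[w > 0].max(initial=0.0)),
                    cfg)
    return DopplerHistogram(_grid(cfg), w @ comps)


def compose_doppler_histogram(model: SkinModelParams,
                              dist: JointPathDistribution,
                              cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Compose the full Doppler histogram H(f) = Σ_n P(n) H_n(f).

    ``dist`` must already be absorption weighted (Beer–Lambert applied).
    The sum over shift counts and the mixture over correlated per-layer path
    lengths are evaluated in closed form through the compound-Poisson
    probability generating function, applied to the FFT of the single-shift
    spectrum — identical to summing P(n) H_n term by term, without the
    truncation.  Shift-count mass at frequencies beyond ±f_max folds back
    (periodic composition); for physiological spectra this mass is far below
    the overflow tolerance.
    """
    cfg = cfg or DopplerConfig()
    h1 = mixture_single_shift(model.speed_distribution("upper"), cfg)

    w2d = dist.marginal_dermis()
    tot = w2d.sum()
    if tot <= 0:
        raise ValueError("path-length distribution has zero weight")
    w2d = w2d / tot
    reps = dist.reps_dermis

    pad = next_fast_len(4 * cfg.n_freq)
    phi = rfft(_two_sided_wrapped(h1.power, pad))

    rate_u, m_u = layer_shift_rates(model.c_blood_upper, model.d_vessels_upper,
                                    cfg.mus_blood)
    rate_l, m_l = layer_shift_rates(model.c_blood_lower, model.d_vessels_lower,
                                    cfg.mus_blood)
    psi_u = np.expm1(m_u * (phi - 1.0))
    psi_l = np.expm1(m_l * (phi - 1.0))
    exp_u = np.exp(np.outer(psi_u * rate_u, reps))  # (n_omega, nL)
    exp_l = np.exp(np.outer(psi_l * rate_l, reps))
    m_omega = np.einsum("wj,jk,wk->w", exp_u, w2d, exp_l, optimize=True)

    h2 = np.maximum(irfft(m_omega, pad), 0.0)
    out = np.empty(cfg.n_freq)
    out[0] = h2[0]
    out[1:] = h2[1:cfg.n_freq] + h2[pad - 1:pad - cfg.n_freq:-1]
    return DopplerHistogram(h1.freq, out / out.sum())


# --------------------------------------------------------------------------
# Biological zero


def biological_zero_bin_mass(freq: np.ndarray, xi_offset: float,
                             xi_slope: float) -> np.ndarray:
    """H_BZ per cell: density 10^(ξ_off + f ξ_slope) × cell width for f > 0,
    exactly 0 at f = 0."""
    df = freq[1] - freq[0]
    out = 10.0 ** (xi_offset + freq * xi_slope) * df
    out[0] = 0.0
    return out


def biological_zero_g1(tau: np.ndarray, xi_offset: float,
                       xi_slope: float) -> tuple[float, np.ndarray]:
    """(total BZ power ε, unnormalized BZ autocorrelation at τ).

    The exponential spectral density transforms to a Lorentzian:
    ∫ A e^{−a f} cos(2πτf) df = A a / (a² + 4π²τ²), a = −ξ_slope ln 10.
    """
    a = -xi_slope * np.log(10.0)
    a = max(a, 1e-12)
    amp = 10.0 ** xi_offset
    eps = amp / a
    return eps, amp * a / (a * a + (2.0 * np.pi * np.asarray(tau)) ** 2)


def add_biological_zero(H: DopplerHistogram, rng: np.random.Generator,
                        cfg: DopplerConfig | None = None) -> DopplerHistogram:
    """Add a randomized biological-zero component and renormalize."""
    cfg = cfg or DopplerConfig()
    off = rng.normal(cfg.bz_offset_mean, cfg.bz_offset_sd) + np.log10(cfg.bz_scale)
    slope = min(rng.normal(cfg.bz_slope_mean, cfg.bz_slope_sd), -1e-9)
    bz = biological_zero_bin_mass(H.freq, off, slope)
    power = H.power + bz
    return DopplerHistogram(H.freq, power / power.sum())


# --------------------------------------------------------------------------
# τ-domain basis for the bulk pipeline


class TauBasis:
    """Single-shift autocorrelations ĝ1_k(τ) of the 10 uniform speed
    components, evaluated in closed form.

    For one component with top speed s, f = c Z with c = (k/π) sin(θ/2) s
    and Z = U·|cosψ| (U, |cosψ| iid uniform), whose density is −ln z, giving
    E[cos(2πfτ)] = Si(a)/a at a = 2π c τ; averaged over equal-probability
    Gegenbauer θ nodes.
    """

    def __init__(self, tau: np.ndarray, top_speeds, cfg: DopplerConfig,
                 n_theta: int = 512):
        self.tau = np.asarray(tau, dtype=float)
        self.cfg = cfg
        mu = gegenbauer_mu_nodes(cfg.gk_g, cfg.gk_alpha, n_theta)
        sin_half = np.sqrt(np.maximum(0.0, (1.0 - mu) / 2.0))
        kpi = _k_over_pi(cfg)
        ghat = np.empty((len(top_speeds), self.tau.size))
        for ki, s in enumerate(top_speeds):
            acc = np.zeros(self.tau.size)
            for a0 in range(0, n_theta, 64):
                a = 2.0 * np.pi * kpi * s * np.outer(sin_half[a0:a0 + 64], self.tau)
                a = np.maximum(a, 1e-12)
                si, _ = sici(a)
                acc += (si / a).sum(axis=0)
            ghat[ki] = acc / n_theta
        self.ghat = ghat  # (10, n_tau)

    def g1_single(self, weights: np.ndarray) -> np.ndarray:
        """ĝ1(τ) of the speed-mixture single-shift spectrum."""
        return weights @ self.ghat

    def g1_model(self, model: SkinModelParams, dist: JointPathDistribution,
                 bz: tuple[float, float] | None = None) -> np.ndarray:
        """Full-model |g¹(τ)| through the shift-count generating functions.

        ``bz`` optionally gives (ξ_offset, ξ_slope) of a biological-zero
        component to mix in.
        """
        g1s = self.g1_single(model.speed_weights)
        w2d = dist.marginal_dermis()
        w2d = w2d / w2d.sum()
        reps = dist.reps_dermis
        cfg = self.cfg
        rate_u, m_u = layer_shift_rates(model.c_blood_upper,
                                        model.d_vessels_upper, cfg.mus_blood)
        rate_l, m_l = layer_shift_rates(model.c_blood_lower,
                                        model.d_vessels_lower, cfg.mus_blood)
        psi_u = np.expm1(m_u * (g1s - 1.0))
        psi_l = np.expm1(m_l * (g1s - 1.0))
        eu = np.exp(np.outer(psi_u * rate_u, reps))  # (n_tau, nL)
        el = np.exp(np.outer(psi_l * rate_l, reps))
        g1 = np.einsum("tj,jk,tk->t", eu, w2d, el, optimize=True)
        if bz is not None:
            eps, gbz = biological_zero_g1(self.tau, *bz)
            g1 = (g1 + gbz) / (1.0 + eps)
        return np.abs(g1)
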