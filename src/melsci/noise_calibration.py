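"""Best-effort calibration of the contrast-noise constants η₁, η_diff(T).

The noise model treats the per-window contrast error as a random walk
across the synthetic-exposure ladder.  This module estimates the walk's
step sizes from first principles: complex Gaussian speckle fields with an
exponentially decorrelating temporal autocorrelation are synthesized frame
by frame (1 ms frames, the instrument's native rate), accumulated into the
synthetic exposures 1..64 ms, and the spatial contrast is computed in small
pixel windows.  η₁ is the relative spread of the 1 ms contrast across
windows; η_diff(T) the relative spread of the *increment* between T and
T/2, both normalized by the mean contrast over all exposures as in the
noise model.

This is a calibration aid; the configured defaults remain the contract for
dataset generation.
"""

from __future__ import annotations

import numpy as np

from .speckle_contrast import EXPOSURES_MS, NoiseParams

__all__ = ["calibrate_noise_constants"]


def calibrate_noise_constants(rng: np.random.Generator,
                              tau_c_ms: float = 20.0,
                              n_pixels: int = 192,
                              window: int = 7,
                              speckles_per_pixel: int = 1) -> NoiseParams:
    """Estimate η₁ and η_diff(T) from synthesized speckle frames.

    ``tau_c_ms`` sets the field decorrelation time (slow relative to the
    frame time so the discrete accumulation approximates continuous
    integration); ``speckles_per_pixel`` averages that many independent
    speckle realizations per pixel, which reduces the noise ∝ 1/√S.
    """
    n_frames = int(EXPOSURES_MS[-1])
    rho = np.exp(-1.0 / tau_c_ms)  # AR(1) per-frame field correlation
    shape = (n_pixels, n_pixels)

    intensity_sum = {int(t): np.zeros(shape) for t in EXPOSURES_MS}
    for _s in range(speckles_per_pixel):
        e = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
        acc = np.zeros(shape)
        for t in range(1, n_frames + 1):
            innov = (rng.standard_normal(shape)
                     + 1j * rng.standard_normal(shape)) / np.sqrt(2)
            e = rho * e + np.sqrt(1.0 - rho * rho) * innov
            acc += np.abs(e) ** 2
            if t in intensity_sum:
                intensity_sum[t] += acc

    # windowed multi-exposure contrast
    nw = n_pixels // window
    K_win = np.empty((nw * nw, len(EXPOSURES_MS)))
    for j, t in enumerate(EXPOSURES_MS):
        img = intensity_sum[int(t)]
        blocks = img[: nw * window, : nw * window].reshape(
            nw, window, nw, window).swapaxes(1, 2).reshape(nw * nw, -1)
        K_win[:, j] = blocks.std(axis=1) / blocks.mean(axis=1)

    mean_K = K_win.mean()
    resid = K_win - K_win.mean(axis=0)
    eta_1 = float(resid[:, 0].std() / mean_K)
    eta_diff = np.array([
        (resid[:, j] - resid[:, j - 1]).std() / mean_K
        for j in range(1, len(EXPOSURES_MS))])
    return NoiseParams(eta_1, eta_diff)
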