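"""Per-pixel perfusion imaging, synthetic image fixtures and ROI statistics.

A multi-exposure contrast image stack is a (H, W, 7) — or (T, H, W, 7) when
time resolved — array of contrast values with the exposure axis labeled
1, 2, 4, 8, 16, 32, 64 ms.  The trained network is applied independently to
every pixel (no spatial coupling), producing maps of the three speed
components and total perfusion in %RBC·mm/s.

The synthetic fixture generator stands in for the instrument: it paints a
scene from per-region tissue models (background plus vessel-like fast
structures, optionally traversing baseline/occlusion/reperfusion phases),
runs the forward model once per distinct region, adds per-pixel contrast
noise, and emits the matching ground-truth perfusion maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .perfusion_ann import AnnModel, predict
from .pipeline import ForwardModel, _swept_model
from .skin_model import SkinModelParams, sample_tissue_model
from .speckle_contrast import EXPOSURES_MS, noisy_contrast_batch

__all__ = [
    "ContrastImageStack",
    "PerfusionImage",
    "predict_image",
    "synth_image_fixture",
    "SceneRegion",
    "ScenePhase",
    "roi_stats",
    "color_scale",
    "temporal_smooth",
]


@dataclass
class ContrastImageStack:
    """Contrast pixels (..., H, W, 7) with the canonical exposure labels."""

    contrast: np.ndarray
    exposures_ms: np.ndarray = field(default_factory=lambda: EXPOSURES_MS.copy())
    intensity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=np.float32)
        if self.contrast.ndim not in (3, 4) or self.contrast.shape[-1] != 7:
            raise ValueError("contrast must be (H, W, 7) or (T, H, W, 7)")
        if not np.array_equal(np.asarray(self.exposures_ms), EXPOSURES_MS):
            raise ValueError("exposure labels must be 1,2,4,8,16,32,64 ms")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("contrast", data=self.contrast)
            f.create_dataset("exposures_ms", data=self.exposures_ms)
            if self.intensity is not None:
                f.create_dataset("intensity", data=self.intensity)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "ContrastImageStack":
        with h5py.File(path, "r") as f:
            return cls(f["contrast"][...], f["exposures_ms"][...],
                       f["intensity"][...] if "intensity" in f else None,
                       dict(f.attrs))


@dataclass
class PerfusionImage:
    """Per-pixel p_low / p_mid / p_high maps (..., H, W, 3), %RBC·mm/s."""

    components: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float32)
        if self.components.shape[-1] != 3:
            raise ValueError("last axis must hold the 3 speed components")

    @property
    def p_total(self) -> np.ndarray:
        return self.components.sum(axis=-1)

    def component(self, name: str) -> np.ndarray:
        idx = {"low": 0, "mid": 1, "high": 2}
        if name == "total":
            return self.p_total
        return self.components[..., idx[name]]

    def rendered(self, name: str) -> np.ndarray:
        """Map for display: negative network outputs clamped to 0 (metrics
        always use the raw values)."""
        return np.maximum(self.component(name), 0.0)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("components", data=self.components)
            f.attrs["units"] = "%RBC*mm/s"
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "PerfusionImage":
        with h5py.File(path, "r") as f:
            return cls(f["components"][...], dict(f.attrs))

    def save_png(self, path, name: str = "total", mask=None,
                 factor: float = 3.0) -> None:
        """Render one component to PNG with the ROI-scaled color range."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = self.rendered(name)
        if img.ndim != 2:
            img = img[0]  # first frame of a time-resolved map
        if mask is None:
            mask = np.zeros(img.shape, dtype=bool)
        lo, hi = color_scale(self, mask, name, factor)
        fig, ax = plt.subplots(figsize=(4, 3))
        im = ax.imshow(img, vmin=lo, vmax=max(hi, 1e-9), cmap="inferno")
        ax.set_axis_off()
        fig.colorbar(im, ax=ax, label=f"{name} perfusion [%RBC·mm/s]")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def predict_image(model: AnnModel, stack: ContrastImageStack) -> PerfusionImage:
    """Vectorized per-pixel forward pass of the network over the stack."""
    c = np.asarray(stack.contrast, dtype=float)
    flat = (c**2).reshape(-1, 7)
    out = predict(model, flat).astype(np.float32)
    return PerfusionImage(out.reshape(c.shape[:-1] + (3,)),
                          {"source": "predict_image"})


# --------------------------------------------------------------------------
# Synthetic scenes


@dataclass
class SceneRegion:
    """One region of a synthetic scene: a mask painter plus parameter
    overrides applied to the scene's sampled base tissue model."""

    name: str
    overrides: dict  # e.g. {"mean_speed": 50.0, "c_blood": 1.0}
    mask_fn: object = None  # callable (H, W) -> bool mask; None = background


@dataclass
class ScenePhase:
    """A temporal phase (e.g. occlusion): global overrides + frame count."""

    name: str
    n_frames: int
    overrides: dict = field(default_factory=dict)


def _apply_overrides(model: SkinModelParams, overrides: dict) -> SkinModelParams:
    for param, value in overrides.items():
        model = _swept_model(model, param, value)
    return model


def synth_image_fixture(fm: ForwardModel, shape: tuple[int, int],
                        regions: list[SceneRegion],
                        rng: np.random.Generator,
                        phases: list[ScenePhase] | None = None,
                        noise: bool = True):
    """Render a synthetic multi-exposure contrast stack with ground truth.

    Every pixel belongs to the last region whose mask covers it (region 0
    must be the full-frame background).  The forward model runs once per
    (region, phase) — identical tissue models are cached by construction —
    and noise is then drawn independently per pixel.

    Returns ``(stack, truth, intensity)`` where ``truth`` is the
    ground-truth PerfusionImage and ``intensity`` a flat unit image.
    """
    H, W = shape
    if not regions or regions[0].mask_fn is not None:
        raise ValueError("regions[0] must be the full-frame background")
    label = np.zeros((H, W), dtype=int)
    for ridx, reg in enumerate(regions[1:], start=1):
        m = np.asarray(reg.mask_fn((H, W)), dtype=bool)
        if m.shape != (H, W):
            raise ValueError("region mask shape mismatch")
        label[m] = ridx

    base = sample_tissue_model(rng, fm.cfg.tissue)
    phases = phases or [ScenePhase("static", 1)]

    frames, truths = [], []
    for phase in phases:
        region_K, region_P = [], []
        for reg in regions:
            model = _apply_overrides(base, {**reg.overrides, **phase.overrides})
            res = fm.evaluate(model, rng, noise=False, bz=True)
            region_K.append(res.contrast_clean)
            region_P.append(res.perfusion.as_array())
        K_clean = np.stack([region_K[r].K for r in label.ravel()])
        truth = np.stack([region_P[r] for r in label.ravel()])
        for _ in range(phase.n_frames):
            if noise:
                Kpix = noisy_contrast_batch(K_clean, fm.noise, rng)
            else:
                Kpix = K_clean
            frames.append(Kpix.reshape(H, W, 7))
            truths.append(truth.reshape(H, W, 3))

    contrast = np.stack(frames) if len(frames) > 1 else frames[0]
    truth_arr = np.stack(truths) if len(truths) > 1 else truths[0]
    stack = ContrastImageStack(contrast,
                               meta={"synthetic": True,
                                     "phases": ",".join(p.name for p in phases)})
    truth_img = PerfusionImage(truth_arr, {"synthetic": True, "truth": True})
    intensity = np.ones((H, W), dtype=np.float32)
    return stack, truth_img, intensity


# --------------------------------------------------------------------------
# ROI statistics and display helpers


def roi_stats(image: PerfusionImage, mask) -> dict:
    """Mean, population SD and CV (%) per component inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    out = {}
    for name in ("low", "mid", "high", "total"):
        vals = image.component(name)[..., mask] if image.components.ndim == 4 \
            else image.component(name)[mask]
        mean = float(vals.mean())
        sd = float(vals.std())  # population convention (divide by N)
        if mean == 0:
            raise ValueError(f"CV undefined: zero mean in component {name}")
        out[name] = {"mean": mean, "sd": sd, "cv_pct": 100.0 * sd / mean}
    return out


def color_scale(image: PerfusionImage, mask, name: str = "total",
                factor: float = 3.0) -> tuple[float, float]:
    """Display range [0, factor × ROI mean] (empty mask → whole-image mean)."""
    mask = np.asarray(mask, dtype=bool)
    comp = image.rendered(name)
    mean = float(comp[..., mask].mean()) if mask.any() else float(comp.mean())
    return (0.0, factor * mean)


def temporal_smooth(series, window_s: float, fs_hz: float) -> np.ndarray:
    """Centered moving average with truncated edge windows."""
    x = np.asarray(series, dtype=float)
    dt = 1.0 / fs_hz
    if window_s < dt:
        raise ValueError("window shorter than the sample interval")
    half = int(round(window_s / dt / 2.0 - 0.5))
    half = max(half, 0)
    n = x.shape[0]
    out = np.empty_like(x)
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        out[i] = x[a:b].mean(axis=0)
    return out
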