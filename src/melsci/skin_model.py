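"""Randomized three-layer skin tissue models and true speed-resolved perfusion.

The model is a bloodless epidermis of variable thickness over two dermis
layers (upper fixed at 0.2 mm, lower semi-infinite) that share one reduced
scattering coefficient and one RBC speed distribution but carry their own
blood tissue fraction, oxygen saturation and vessel diameter.  The RBC speed
distribution is a weighted sum of 10 uniform distributions from 0 mm/s to
exponentially increasing top speeds — each component being the speed profile
of parabolic flow in a vessel with a given average speed.

True perfusion in a speed band [vmin, vmax] is the first moment of the RBC
concentration-by-speed density over that band,

    P[vmin, vmax] = ∫ v c_RBC(v) dv   (%RBC · mm/s),

weighted per layer by the fraction of detected photon path length the layer
contributes (its share of the sampling volume); the epidermis contributes
zero perfusion but still dilutes the sampling volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import TissueConfig

__all__ = [
    "SpeedDistribution",
    "SkinModelParams",
    "SpeedResolvedPerfusion",
    "build_speed_distribution",
    "sample_tissue_model",
    "tilt_weights_to_mean",
    "true_perfusion",
    "SPEED_BANDS",
]

#: the three reported speed bands, mm/s
SPEED_BANDS = ((0.0, 1.0), (1.0, 10.0), (10.0, np.inf))


@dataclass
class SpeedDistribution:
    """Mixture of uniform speed components scaled to a total RBC fraction.

    The density is ``c_RBC(v) = c_blood * sum_k w_k / top_k`` for
    ``v < top_k`` — piecewise constant, nonincreasing, integrating to
    ``c_blood`` (in %RBC).
    """

    top_speeds: np.ndarray  # mm/s
    weights: np.ndarray  # normalized, sum 1
    c_blood: float  # %

    def __post_init__(self) -> None:
        self.top_speeds = np.asarray(self.top_speeds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def mean_speed(self) -> float:
        """⟨v_RBC⟩ = Σ w_k top_k / 2 (uniform components), mm/s."""
        return float(np.sum(self.weights * self.top_speeds) / 2.0)

    def density(self, v) -> np.ndarray:
        """c_RBC(v) in %RBC per (mm/s)."""
        v = np.atleast_1d(np.asarray(v, dtype=float))
        out = np.zeros_like(v)
        for w, top in zip(self.weights, self.top_speeds):
            out += np.where(v < top, w / top, 0.0)
        return self.c_blood * out

    def band_perfusion(self, vmin: float, vmax: float) -> float:
        """∫_vmin^vmax v c_RBC(v) dv, %RBC·mm/s (closed form per component)."""
        if vmin < 0 or vmax < vmin:
            raise ValueError("need 0 <= vmin <= vmax")
        hi = np.minimum(self.top_speeds, vmax)
        lo = np.minimum(self.top_speeds, vmin)
        integ = (hi**2 - lo**2) / (2.0 * self.top_speeds)
        return float(self.c_blood * np.sum(self.weights * integ))


@dataclass
class SkinModelParams:
    """One realization of the randomized three-layer skin model."""

    t_epi: float  # mm
    mua_epi: float  # mm^-1
    musp: float  # mm^-1, shared by all layers
    c_blood_upper: float  # %
    c_blood_lower: float  # %
    s_oxy_upper: float  # fraction
    s_oxy_lower: float  # fraction
    d_vessels_upper: float  # mm
    d_vessels_lower: float  # mm
    speed_weights: np.ndarray  # 10 mixture weights, sum 1
    top_speeds: np.ndarray = field(
        default_factory=lambda: np.array([0.5 * 2.0**k for k in range(10)])
    )
    t_dermis_upper: float = 0.2  # mm, fixed

    def __post_init__(self) -> None:
        self.speed_weights = np.asarray(self.speed_weights, dtype=float)
        self.top_speeds = np.asarray(self.top_speeds, dtype=float)
        if self.t_epi <= 0 or self.musp <= 0:
            raise ValueError("t_epi and musp must be positive")
        if not (0 <= self.s_oxy_upper <= 1 and 0 <= self.s_oxy_lower <= 1):
            raise ValueError("oxygen saturation outside [0, 1]")
        if min(self.c_blood_upper, self.c_blood_lower) < 0:
            raise ValueError("blood fraction must be nonnegative")
        if min(self.d_vessels_upper, self.d_vessels_lower) <= 0:
            raise ValueError("vessel diameter must be positive")
        s = self.speed_weights.sum()
        if s <= 0 or np.any(self.speed_weights < 0):
            raise ValueError("speed weights must be nonnegative, not all zero")
        self.speed_weights = self.speed_weights / s

    def speed_distribution(self, layer: str) -> SpeedDistribution:
        c = {"upper": self.c_blood_upper, "lower": self.c_blood_lower}[layer]
        return SpeedDistribution(self.top_speeds, self.speed_weights, c)


@dataclass
class SpeedResolvedPerfusion:
    """Perfusion in the bands 0–1, 1–10, >10 mm/s plus their sum, %RBC·mm/s."""

    p_low: float
    p_mid: float
    p_high: float

    @property
    def p_total(self) -> float:
        return self.p_low + self.p_mid + self.p_high

    def as_array(self) -> np.ndarray:
        return np.array([self.p_low, self.p_mid, self.p_high])


def build_speed_distribution(weights, c_blood: float, top_speeds=None) -> SpeedDistribution:
    """Normalize 10 nonnegative weights into a uniform-mixture speed density."""
    w = np.asarray(weights, dtype=float)
    if top_speeds is None:
        top_speeds = np.array([0.5 * 2.0**k for k in range(10)])
    top_speeds = np.asarray(top_speeds, dtype=float)
    if w.shape != top_speeds.shape:
        raise ValueError("weights and top_speeds must have equal length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    if c_blood < 0:
        raise ValueError("c_blood must be nonnegative")
    return SpeedDistribution(top_speeds, w / w.sum(), float(c_blood))


def tilt_weights_to_mean(weights, top_speeds, target_mean: float) -> np.ndarray:
    """Exponentially tilt mixture weights so that Σ w_k top_k / 2 = target.

    Tilting (``w_k ∝ w_k exp(s·log2 top_k)``) preserves the relative shape
    of the randomized weights while steering the mean speed; it is also the
    mechanism behind the mean-speed sweep experiments.
    """
    w0 = np.asarray(weights, dtype=float)
    tops = np.asarray(top_speeds, dtype=float)
    w0 = w0 / w0.sum()
    half = tops / 2.0
    lo, hi = half.min(), half.max()
    if not (lo < target_mean < hi):
        raise ValueError(f"target mean {target_mean} outside attainable ({lo}, {hi})")
    x = np.log2(tops)

    def mean_at(s: float) -> float:
        ww = w0 * np.exp(s * (x - x.mean()))
        ww /= ww.sum()
        return float(np.sum(ww * half))

    s = optimize.brentq(lambda s: mean_at(s) - target_mean, -60.0, 60.0, xtol=1e-12)
    w = w0 * np.exp(s * (x - x.mean()))
    return w / w.sum()


def _layer_pair(rng: np.random.Generator, avg: float, diff_frac: float,
                clip=None) -> tuple[float, float]:
    # randomized average + randomized bounded difference: layers get
    # avg ± d/2 with d uniform in ±diff_frac·avg
    d = avg * diff_frac * (2.0 * rng.random() - 1.0)
    upper, lower = avg + d / 2.0, avg - d / 2.0
    if clip is not None:
        upper = float(np.clip(upper, *clip))
        lower = float(np.clip(lower, *clip))
    return upper, lower


def sample_tissue_model(rng: np.random.Generator, cfg: TissueConfig | None = None,
                        restricted: bool | None = None) -> SkinModelParams:
    """Draw one randomized skin model from the configured distributions.

    With ``restricted=True`` the parameters not directly determining
    perfusion (t_epi, musp, mua_epi, d_vessels, s_oxy) are frozen at their
    configured medians; blood fraction and the speed distribution still vary.
    """
    cfg = cfg or TissueConfig()
    if restricted is None:
        restricted = cfg.restricted
    d = cfg.dists
    tops = np.asarray(cfg.top_speeds)

    if restricted:
        t_epi = d["t_epi"].median
        mua_epi = d["mua_epi"].median
        musp = d["musp"].median
        s_up = s_lo = d["s_oxy"].median
        dv_up = dv_lo = d["d_vessels"].median
    else:
        t_epi = float(d["t_epi"].sample(rng))
        mua_epi = float(d["mua_epi"].sample(rng))
        musp = float(d["musp"].sample(rng))
        s_up, s_lo = _layer_pair(rng, float(d["s_oxy"].sample(rng)),
                                 cfg.layer_diff_frac, clip=(0.0, 1.0))
        dv_up, dv_lo = _layer_pair(rng, float(d["d_vessels"].sample(rng)),
                                   cfg.layer_diff_frac)

    c_avg = float(d["c_blood"].sample(rng))
    c_up, c_lo = _layer_pair(rng, c_avg, cfg.layer_diff_frac)

    raw_w = rng.dirichlet(np.full(len(tops), cfg.dirichlet_alpha))
    target = float(d["mean_speed"].sample(rng))
    weights = tilt_weights_to_mean(raw_w + 1e-12, tops, target)

    return SkinModelParams(
        t_epi=t_epi, mua_epi=mua_epi, musp=musp,
        c_blood_upper=c_up, c_blood_lower=c_lo,
        s_oxy_upper=s_up, s_oxy_lower=s_lo,
        d_vessels_upper=dv_up, d_vessels_lower=dv_lo,
        speed_weights=weights, top_speeds=tops,
        t_dermis_upper=cfg.t_dermis_upper,
    )


def true_perfusion(model: SkinModelParams, sampling_weights) -> SpeedResolvedPerfusion:
    """Speed-resolved perfusion weighted by each layer's sampling-volume share.

    ``sampling_weights`` is the (epidermis, upper dermis, lower dermis)
    fraction of absorption-weighted detected photon path length; it must be
    nonnegative and sum to 1.
    """
    w = np.asarray(sampling_weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("sampling_weights must have 3 entries")
    if np.any(w < 0):
        raise ValueError("sampling weights must be nonnegative")
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("sampling weights must sum to 1")

    bands = np.zeros(3)
    for w_layer, layer in zip(w[1:], ("upper", "lower")):
        sd = model.speed_distribution(layer)
        for j, (a, b) in enumerate(SPEED_BANDS):
            bands[j] += w_layer * sd.band_perfusion(a, min(b, 1e9))
    return SpeedResolvedPerfusion(*bands)
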