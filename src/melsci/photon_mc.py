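"""Monte Carlo photon transport in the three-layer slab.

Photons are launched normally onto the surface and random-walked without
absorption; the geometric path length accumulated in each layer is recorded
for every photon that escapes through the top surface (wide-field detection:
every exit counts, as each pixel of a full-field imager reads diffuse
reflectance).  Absorption is applied afterwards with Beer–Lambert weights,
which requires the *joint* per-layer path-length distribution — stored here
as a 3-D histogram per grid node.

Transport by default uses the similarity relation: isotropic deflections at
the reduced scattering coefficient μs′, which reproduces the diffuse
path-length statistics of the strongly forward-peaked tissue phase function
at a small fraction of the cost.  Transport with explicit Gegenbauer-kernel
deflections at the full scattering coefficient μs′/(1−g) is available via
``MCConfig.transport_phase = "gegenbauer"``.

The refractive index step at the surface (tissue 1.4 / air 1.0) is honored
with unpolarized Fresnel reflection and total internal reflection; internal
boundaries are index matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numba
import numpy as np

from .config import MCConfig

__all__ = [
    "PathLengthTable",
    "JointPathDistribution",
    "run_mc_grid",
    "interpolate_pathlengths",
    "apply_absorption",
    "dermis_absorption",
    "vessel_packing_factor",
    "mua_blood",
]


@numba.njit(cache=True, inline="always")
def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Reflectance for internal incidence, tissue (n_rel) -> outside (1)."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@numba.njit(cache=True, inline="always")
def _gk_sample_mu(u: float, g: float, alpha: float) -> float:
    """Inverse-CDF sample of cos(theta) for the Gegenbauer kernel."""
    lo = (1.0 + g) ** (-2.0 * alpha)  # value of (1+g^2-2g mu)^-alpha at mu=-1
    hi = (1.0 - g) ** (-2.0 * alpha)  # at mu=+1
    t = lo + u * (hi - lo)
    return (1.0 + g * g - t ** (-1.0 / alpha)) / (2.0 * g)


@numba.njit(cache=True)
def _transport_kernel(n_photons, t_epi, t_up, mus, n_rel, max_path, seed,
                      log_e1, log_e2, log_e3, hist, use_gk, gk_g, gk_alpha):
    """Walk photons; fill the joint (l1, l2, l3) histogram of detected ones.

    Returns (n_detected, n_killed, sum_l1, sum_l2, sum_l3) over detected
    photons.  Layer-2/3 axes carry bin 0 as "exactly zero path".
    """
    np.random.seed(seed)
    z1 = t_epi
    z2 = t_epi + t_up
    n1 = log_e1.shape[0] - 1
    n2 = log_e2.shape[0] - 1
    n3 = log_e3.shape[0] - 1

    n_det = 0
    n_kill = 0
    s1 = 0.0
    s2 = 0.0
    s3 = 0.0

    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        l1 = 0.0
        l2 = 0.0
        l3 = 0.0
        alive = True
        detected = False

        while alive:
            step = -np.log(np.random.random()) / mus
            while step > 0.0:
                # distance to the nearest boundary along z
                if uz < -1e-12:
                    if z > z2:
                        db = (z2 - z) / uz
                        nxt = 2
                    elif z > z1:
                        db = (z1 - z) / uz
                        nxt = 1
                    else:
                        db = (0.0 - z) / uz
                        nxt = 0
                elif uz > 1e-12:
                    if z < z1:
                        db = (z1 - z) / uz
                        nxt = 1
                    elif z < z2:
                        db = (z2 - z) / uz
                        nxt = 2
                    else:
                        db = 1e30
                        nxt = -1
                else:
                    db = 1e30
                    nxt = -1

                seg = step if step < db else db
                # accumulate path in the current layer
                if z < z1 or (z == z1 and uz < 0.0):
                    l1 += seg
                elif z < z2 or (z == z2 and uz < 0.0):
                    l2 += seg
                else:
                    l3 += seg

                z += uz * seg
                step -= seg

                if step > 0.0:
                    # hit a boundary with travel remaining
                    if nxt == 0:
                        # top surface: Fresnel
                        cos_i = -uz
                        refl = _fresnel_unpolarized(cos_i, n_rel)
                        if np.random.random() >= refl:
                            detected = True
                            alive = False
                            break
                        uz = -uz
                        z = 0.0
                    else:
                        # matched internal boundary: continue straight
                        if nxt == 1:
                            z = z1
                        elif nxt == 2:
                            z = z2
                else:
                    break

            if not alive:
                break
            if l1 + l2 + l3 > max_path:
                n_kill += 1
                alive = False
                break

            # scatter
            if use_gk:
                mu_s = _gk_sample_mu(np.random.random(), gk_g, gk_alpha)
            else:
                mu_s = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            sin_s = np.sqrt(max(0.0, 1.0 - mu_s * mu_s))
            cphi = np.cos(phi)
            sphi = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_s * cphi
                uy = sin_s * sphi
                uz = mu_s * (1.0 if uz > 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = sin_s * (ux * uz * cphi - uy * sphi) / den + ux * mu_s
                uy_n = sin_s * (uy * uz * cphi + ux * sphi) / den + uy * mu_s
                uz_n = -sin_s * cphi * den + uz * mu_s
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

        if detected:
            n_det += 1
            s1 += l1
            s2 += l2
            s3 += l3
            # bin: layer 1 log bins (l1 always > 0 for detected photons)
            b1 = _log_bin(l1, log_e1, n1)
            b2 = _zero_or_log_bin(l2, log_e2, n2)
            b3 = _zero_or_log_bin(l3, log_e3, n3)
            hist[b1, b2, b3] += 1.0

    return n_det, n_kill, s1, s2, s3


@numba.njit(cache=True, inline="always")
def _log_bin(val: float, log_edges, n: int) -> int:
    x = np.log(val)
    if x <= log_edges[0]:
        return 0
    if x >= log_edges[n]:
        return n - 1
    return int(np.searchsorted(log_edges, x) - 1)


@numba.njit(cache=True, inline="always")
def _zero_or_log_bin(val: float, log_edges, n: int) -> int:
    # axis layout: index 0 = exactly zero, 1..n = log bins
    if val <= 0.0:
        return 0
    return 1 + _log_bin(val, log_edges, n)


@dataclass
class PathLengthTable:
    """Joint per-layer path-length histograms on a (t_epi, musp) grid."""

    grid_t_epi: np.ndarray
    grid_musp: np.ndarray
    edges_epi: np.ndarray  # mm, n1+1 log-spaced edges
    edges_dermis: np.ndarray  # mm, shared by both dermis layers
    counts: np.ndarray  # (nt, nm, n1, n2+1, n3+1) detected-photon counts
    n_photons: int
    n_detected: np.ndarray  # (nt, nm)
    n_killed: np.ndarray
    seed: int
    meta: dict

    @property
    def reps_epi(self) -> np.ndarray:
        """Representative (geometric-center) path length per epidermis bin."""
        e = self.edges_epi
        return np.sqrt(e[:-1] * e[1:])

    @property
    def reps_dermis(self) -> np.ndarray:
        e = self.edges_dermis
        return np.concatenate([[0.0], np.sqrt(e[:-1] * e[1:])])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("grid_t_epi", "grid_musp", "edges_epi",
                         "edges_dermis", "counts", "n_detected", "n_killed"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["n_photons"] = self.n_photons
            f.attrs["seed"] = self.seed
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "PathLengthTable":
        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("grid_t_epi", "grid_musp", "edges_epi", "edges_dermis",
                   "counts", "n_detected", "n_killed")}
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(n_photons=int(f.attrs["n_photons"]),
                       seed=int(f.attrs["seed"]), meta=meta, **kw)


@dataclass
class JointPathDistribution:
    """Normalized joint (l1, l2, l3) histogram at one (t_epi, musp) point."""

    hist: np.ndarray  # (n1, n2+1, n3+1), sums to 1 (before absorption)
    reps_epi: np.ndarray
    reps_dermis: np.ndarray

    @property
    def weight_total(self) -> float:
        return float(self.hist.sum())

    def layer_path_fractions(self) -> np.ndarray:
        """Fraction of (weighted) total path length per layer — the
        sampling-volume weights for true perfusion."""
        w = self.hist
        tot1 = float(np.einsum("ijk,i->", w, self.reps_epi))
        tot2 = float(np.einsum("ijk,j->", w, self.reps_dermis))
        tot3 = float(np.einsum("ijk,k->", w, self.reps_dermis))
        s = tot1 + tot2 + tot3
        return np.array([tot1, tot2, tot3]) / s

    def marginal_dermis(self) -> np.ndarray:
        """Joint (l2, l3) weights after collapsing the epidermis axis."""
        return self.hist.sum(axis=0)


def run_mc_grid(cfg: MCConfig | None = None, seed: int = 0,
                progress: bool = False) -> PathLengthTable:
    """Simulate the (t_epi, musp) grid and return the path-length table."""
    cfg = cfg or MCConfig()
    gt = np.asarray(cfg.grid_t_epi, dtype=float)
    gm = np.asarray(cfg.grid_musp, dtype=float)
    if cfg.n_photons < 10_000:
        raise ValueError("need at least 1e4 photons per grid node")
    use_gk = cfg.transport_phase == "gegenbauer"
    if cfg.transport_phase not in ("isotropic-reduced", "gegenbauer"):
        raise ValueError(f"unknown transport_phase {cfg.transport_phase!r}")

    edges_epi = np.geomspace(*cfg.l_epi_range, cfg.n_bins_epi + 1)
    edges_dermis = np.geomspace(*cfg.l_dermis_range, cfg.n_bins_dermis + 1)
    log_e1 = np.log(edges_epi)
    log_e23 = np.log(edges_dermis)

    nt, nm = len(gt), len(gm)
    counts = np.zeros((nt, nm, cfg.n_bins_epi, cfg.n_bins_dermis + 1,
                       cfg.n_bins_dermis + 1))
    n_det = np.zeros((nt, nm), dtype=np.int64)
    n_kill = np.zeros((nt, nm), dtype=np.int64)
    n_rel = cfg.n_tissue / cfg.n_outside

    ss = np.random.SeedSequence(seed)
    node_seeds = ss.generate_state(nt * nm)
    if use_gk:
        from .doppler_spectrum import gegenbauer_anisotropy
        g_aniso = gegenbauer_anisotropy(cfg.gk_g, cfg.gk_alpha)
    for i, t_epi in enumerate(gt):
        for j, musp in enumerate(gm):
            mus = musp if not use_gk else musp / (1.0 - g_aniso)
            hist = counts[i, j]
            d, k, *_ = _transport_kernel(
                cfg.n_photons, t_epi, 0.2, mus, n_rel, cfg.max_path_mm,
                node_seeds[i * nm + j] & 0x7FFFFFFF, log_e1, log_e23, log_e23,
                hist, use_gk, cfg.gk_g, cfg.gk_alpha)
            n_det[i, j] = d
            n_kill[i, j] = k
            if progress:
                print(f"node t_epi={t_epi:.3f} musp={musp:.3f}: "
                      f"{d}/{cfg.n_photons} detected")

    meta = {"transport_phase": cfg.transport_phase,
            "max_path_mm": cfg.max_path_mm, "n_tissue": cfg.n_tissue}
    return PathLengthTable(gt, gm, edges_epi, edges_dermis, counts,
                           cfg.n_photons, n_det, n_kill, seed, meta)


def _bracket(grid: np.ndarray, x: float, name: str) -> tuple[int, float]:
    if x < grid[0] - 1e-12 or x > grid[-1] + 1e-12:
        raise ValueError(
            f"{name}={x} outside the table grid [{grid[0]}, {grid[-1]}]; "
            "no extrapolation")
    x = float(np.clip(x, grid[0], grid[-1]))
    i = int(np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2))
    # interpolate linearly in log of the grid variable (grids are log-spaced)
    frac = (np.log(x) - np.log(grid[i])) / (np.log(grid[i + 1]) - np.log(grid[i]))
    return i, float(frac)


def interpolate_pathlengths(table: PathLengthTable, t_epi: float,
                            musp: float) -> JointPathDistribution:
    """Bilinear interpolation of the normalized joint histograms.

    At a grid node the stored (normalized) histogram is returned exactly;
    queries outside the grid raise (no extrapolation).
    """
    i, fi = _bracket(table.grid_t_epi, t_epi, "t_epi")
    j, fj = _bracket(table.grid_musp, musp, "musp")

    out = np.zeros(table.counts.shape[2:])
    for di, wi in ((0, 1 - fi), (1, fi)):
        for dj, wj in ((0, 1 - fj), (1, fj)):
            w = wi * wj
            if w == 0.0:
                continue
            h = table.counts[i + di, j + dj]
            s = h.sum()
            if s == 0:
                raise RuntimeError("empty histogram at grid node")
            out += w * (h / s)
    return JointPathDistribution(out, table.reps_epi, table.reps_dermis)


def apply_absorption(dist: JointPathDistribution, mua_epi: float,
                     mua_dermis_upper: float,
                     mua_dermis_lower: float) -> JointPathDistribution:
    """Beer–Lambert reweighting exp(−Σ μa,i l_i) of the joint histogram.

    The output keeps relative weights (it is *not* renormalized; total
    weight is the surviving detected fraction relative to the input).
    """
    for mua in (mua_epi, mua_dermis_upper, mua_dermis_lower):
        if mua < 0:
            raise ValueError("absorption coefficients must be nonnegative")
    w1 = np.exp(-mua_epi * dist.reps_epi)
    w2 = np.exp(-mua_dermis_upper * dist.reps_dermis)
    w3 = np.exp(-mua_dermis_lower * dist.reps_dermis)
    hist = dist.hist * w1[:, None, None] * w2[None, :, None] * w3[None, None, :]
    return JointPathDistribution(hist, dist.reps_epi, dist.reps_dermis)


def mua_blood(s_oxy: float, mua_oxy: float = 0.38,
              mua_deoxy: float = 0.576) -> float:
    """Whole-blood absorption at 780 nm, linear oxy/deoxy mixing, mm^-1."""
    if not (0.0 <= s_oxy <= 1.0):
        raise ValueError("oxygen saturation outside [0, 1]")
    return s_oxy * mua_oxy + (1.0 - s_oxy) * mua_deoxy


def vessel_packing_factor(d_vessels: float, mua_b: float) -> float:
    """Cylindrical vessel-packaging correction C_pack ∈ (0, 1].

    C_pack = (1 − exp(−2 μa,blood R)) / (2 μa,blood R), R = d/2: the mean
    attenuation a beam experiences crossing an absorbing cylinder relative
    to the homogeneous limit.  d → 0 gives 1.
    """
    if d_vessels < 0 or mua_b < 0:
        raise ValueError("inputs must be nonnegative")
    x = mua_b * d_vessels  # = 2 mua R
    if x < 1e-12:
        return 1.0
    return float(-np.expm1(-x) / x)


def dermis_absorption(c_blood: float, s_oxy: float, d_vessels: float,
                      mua_oxy: float = 0.38, mua_deoxy: float = 0.576,
                      mua_baseline: float = 0.02) -> float:
    """Dermis absorption coefficient, mm^-1.

    μa = c C_pack μa,blood + (1 − c) μa,baseline with c the RBC tissue
    fraction (``c_blood`` given in %), packaged for vessels of diameter
    ``d_vessels`` (mm).
    """
    if c_blood < 0:
        raise ValueError("blood fraction must be nonnegative")
    c = c_blood / 100.0
    mb = mua_blood(s_oxy, mua_oxy, mua_deoxy)
    cp = vessel_packing_factor(d_vessels, mb)
    return c * cp * mb + (1.0 - c) * mua_baseline
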