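"""Doppler spectra: phase function, shift composition, biological zero."""

import numpy as np
import pytest

from melsci.config import DopplerConfig
from melsci.doppler_spectrum import (DopplerHistogram, GridOverflowError,
                                     TauBasis, add_biological_zero,
                                     biological_zero_bin_mass,
                                     compose_doppler_histogram,
                                     gegenbauer_anisotropy,
                                     layer_shift_rates, n_shift_histogram,
                                     shift_count_distribution,
                                     single_shift_histogram,
                                     single_shift_histogram_uniform)
from melsci.photon_mc import apply_absorption, interpolate_pathlengths
from melsci.skin_model import SkinModelParams

SMALL = DopplerConfig(n_freq=2**12, f_max_hz=1e5, n_theta=1024)


def _model(weights, c=0.6, d=0.055):
    return SkinModelParams(
        t_epi=0.2, mua_epi=0.3, musp=1.6, c_blood_upper=c, c_blood_lower=c,
        s_oxy_upper=0.5, s_oxy_lower=0.5, d_vessels_upper=d, d_vessels_lower=d,
        speed_weights=np.asarray(weights))


class TestGegenbauer:
    def test_reference_anisotropy_value(self):
        assert gegenbauer_anisotropy(0.948, 1.0) == pytest.approx(0.991,
                                                                  abs=1e-3)

    def test_isotropic_limit(self):
        assert gegenbauer_anisotropy(1e-5, 1.0) == pytest.approx(0.0, abs=1e-4)

    def test_henyey_greenstein_reduction(self):
        # alpha = 1/2 is Henyey–Greenstein, whose mean cosine is exactly g
        for g in (0.3, 0.7, 0.948):
            assert gegenbauer_anisotropy(g, 0.5) == pytest.approx(g, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gegenbauer_anisotropy(1.2, 1.0)
        with pytest.raises(ValueError):
            gegenbauer_anisotropy(0.9, -0.6)


class TestSingleShift:
    def test_zero_speed_is_unshifted_delta(self):
        h = single_shift_histogram(0.0, SMALL)
        assert h.power[0] == 1.0
        assert h.power[1:].sum() == 0.0

    def test_normalized_and_bandlimited(self):
        v = 10.0  # mm/s
        h = single_shift_histogram(v, SMALL)
        assert h.power.sum() == pytest.approx(1.0, abs=1e-9)
        f_max = 2 * SMALL.n_tissue * v / (SMALL.wavelength_nm * 1e-6)  # Hz
        assert h.power[h.freq > f_max * 1.001].sum() == 0.0
        assert h.power[h.freq < f_max].sum() > 0.999

    def test_overflow_raises_with_required_fmax(self):
        cfg = DopplerConfig(n_freq=2**10, f_max_hz=1e4, overflow_tol=1e-3)
        with pytest.raises(GridOverflowError) as exc:
            single_shift_histogram(50.0, cfg)
        assert exc.value.required_f_max > 1e4

    def test_quadrature_matches_monte_carlo_sampling(self, rng):
        v = 5.0
        h = single_shift_histogram(v, SMALL)
        n = 1_000_000
        from melsci.doppler_spectrum import _gk_ppf

        theta_mu = _gk_ppf(rng.random(n), SMALL.gk_g, SMALL.gk_alpha)
        sin_half = np.sqrt((1 - theta_mu) / 2)
        kpi = 2 * SMALL.n_tissue / (SMALL.wavelength_nm * 1e-6)
        f = kpi * sin_half * v * np.abs(rng.uniform(-1, 1, n))
        # compare on coarse bins: 3 SE per bin
        edges = np.linspace(0, SMALL.f_max_hz, 33)
        obs, _ = np.histogram(f, bins=edges)
        exp = np.array([h.power[(h.freq >= a) & (h.freq < b)].sum()
                        for a, b in zip(edges[:-1], edges[1:])]) * n
        se = np.sqrt(np.maximum(exp, 1.0))
        # 3 SE per coarse bin, plus a 10-count (1e-5 mass) allowance for the
        # partial tail bin where the midpoint theta nodes clip the supremum
        assert np.all(np.abs(obs - exp) <= 3 * se + 10.0)

    def test_uniform_component_softens_spectrum(self):
        hp = single_shift_histogram(8.0, SMALL)
        hu = single_shift_histogram_uniform(8.0, SMALL)
        assert hu.power.sum() == pytest.approx(1.0, abs=1e-9)
        # averaging speeds U(0, v) moves mass toward low frequencies
        cdf_p = np.cumsum(hp.power)
        cdf_u = np.cumsum(hu.power)
        assert np.all(cdf_u - cdf_p >= -1e-12)


class TestNShift:
    def test_two_point_spectrum_convolution(self):
        cfg = DopplerConfig(n_freq=64, f_max_hz=63.0, overflow_tol=1e-3)
        freq = np.linspace(0, 63, 64)
        power = np.zeros(64)
        power[10] = 1.0  # two-sided: ±f0 at 0.5 each
        h2 = n_shift_histogram(DopplerHistogram(freq, power), 2, cfg)
        assert h2.power[0] == pytest.approx(0.5)
        assert h2.power[20] == pytest.approx(0.5)
        assert h2.power.sum() == pytest.approx(1.0)

    def test_single_fold_is_identity(self):
        h = single_shift_histogram(3.0, SMALL)
        h1 = n_shift_histogram(h, 1, SMALL)
        assert np.array_equal(h1.power, h.power)

    def test_normalization_preserved_for_many_folds(self):
        h = single_shift_histogram(1.0, SMALL)
        for n in (2, 5, 16, 48):
            hn = n_shift_histogram(h, n, SMALL)
            assert hn.power.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(hn.power >= 0)

    def test_overflow_beyond_grid_detected(self):
        cfg = DopplerConfig(n_freq=2**10, f_max_hz=2e4, overflow_tol=1e-4)
        h = single_shift_histogram(5.0, cfg)
        with pytest.raises(GridOverflowError):
            n_shift_histogram(h, 40, cfg)


class TestShiftCounts:
    def test_no_blood_means_no_shifts(self):
        d = shift_count_distribution([1.0, 2.0], [0.5, 0.5], 0.0, 0.055)
        assert d.probs[0] == pytest.approx(1.0)

    def test_homogeneous_limit_is_plain_poisson(self):
        from scipy.stats import poisson

        l, c, mus_b = 1.5, 0.8, 222.0
        d = shift_count_distribution([l], [1.0], c, 1e-6, mus_b)
        lam = l * c / 100 * mus_b
        ref = poisson.pmf(np.arange(d.probs.size), lam)
        assert np.abs(d.probs - ref).sum() / 2 < 1e-3  # total variation

    def test_vessel_packaging_overdisperses_counts(self):
        l, w = [2.0], [1.0]
        d_small = shift_count_distribution(l, w, 0.6, 1e-6)
        d_pack = shift_count_distribution(l, w, 0.6, 0.1)
        assert d_small.variance / d_small.mean == pytest.approx(1.0, abs=0.02)
        assert d_pack.variance / d_pack.mean > 2.0
        # mean shift count is the same homogeneous value in both cases
        assert d_pack.mean == pytest.approx(d_small.mean, rel=0.02)

    def test_rates_product_equals_homogeneous_rate(self):
        rate, m = layer_shift_rates(0.55, 0.055, 222.0)
        assert rate * m == pytest.approx(0.0055 * 222.0)


class TestCompose:
    def _dist(self, fm):
        d = interpolate_pathlengths(fm.table, 0.2, 1.6)
        return apply_absorption(d, 0.3, 0.1, 0.1)

    def test_no_blood_gives_pure_delta(self, fm_small):
        m = _model([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], c=0.0)
        h = compose_doppler_histogram(m, self._dist(fm_small), SMALL)
        assert h.power[0] == pytest.approx(1.0, abs=1e-12)

    def test_power_normalized(self, fm_small):
        m = _model([0.1, 0.3, 0.3, 0.2, 0.1, 0, 0, 0, 0, 0])
        h = compose_doppler_histogram(m, self._dist(fm_small), SMALL)
        assert h.power.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.power >= 0)

    def test_zero_shift_weight_matches_count_statistics(self, fm_small):
        # weight of the f=0 bin ≈ joint probability of zero shifts in both
        # dermis layers, mixed over the correlated path-length cells
        m = _model([0, 0, 0, 0.4, 0.4, 0.2, 0, 0, 0, 0])  # fast-ish speeds
        dist = self._dist(fm_small)
        h = compose_doppler_histogram(m, dist, SMALL)
        w2d = dist.marginal_dermis()
        w2d = w2d / w2d.sum()
        reps = dist.reps_dermis
        rate, mshift = layer_shift_rates(m.c_blood_upper, m.d_vessels_upper,
                                         SMALL.mus_blood)
        p0 = np.exp(-rate * reps * -np.expm1(-mshift))
        expected = float(p0 @ w2d @ p0)
        assert h.zero_shift_weight == pytest.approx(expected, abs=2e-3)

    def test_doubling_speeds_rescales_spectrum(self, fm_small):
        # doubling every speed = shifting mixture weights one component up
        # (top speeds are powers of two): H2(2f) should equal H1(f)
        w1 = np.array([0, 0.5, 0.3, 0.2, 0, 0, 0, 0, 0, 0.0])
        w2 = np.roll(w1, 1)
        fine = DopplerConfig(n_freq=2**13, f_max_hz=5e4, n_theta=1024)
        dist = self._dist(fm_small)
        h1 = compose_doppler_histogram(_model(w1), dist, fine)
        h2 = compose_doppler_histogram(_model(w2), dist, fine)
        c1 = np.cumsum(h1.power)
        c2 = np.cumsum(h2.power)
        # compare CDFs at f and 2f on the refined grid, above the lowest
        # few cells where finite bin width dominates
        idx = np.arange(16, fine.n_freq // 2)
        assert np.abs(c2[2 * idx] - c1[idx]).max() < 1e-3

    def test_tau_route_matches_gridded_route(self, fm_small):
        m = _model([0.05, 0.2, 0.3, 0.25, 0.1, 0.05, 0.05, 0, 0, 0])
        dist = self._dist(fm_small)
        cfg = fm_small.cfg.doppler
        h = compose_doppler_histogram(m, dist, cfg)
        # the gridded route resolves g1 only for tau << 1/df; compare there
        keep = fm_small.tau <= 2e-3
        g1_hist = h.g1(fm_small.tau[keep])
        g1_tau = fm_small.basis.g1_model(m, dist)[keep]
        assert np.abs(g1_hist - g1_tau).max() < 2e-3


class TestBiologicalZero:
    def test_zero_frequency_bin_stays_empty(self):
        f = np.linspace(0, 1e5, 512)
        bz = biological_zero_bin_mass(f, -5.3, -5.2e-5)
        assert bz[0] == 0.0
        assert np.all(np.diff(bz[1:]) < 0)  # monotone decreasing for f > 0

    def test_mean_parameter_spectral_shape(self):
        f = np.array([0.0, 1e4, 5e4])
        bz = biological_zero_bin_mass(f, -5.3, -5.2e-5)
        df = f[1] - f[0]
        assert bz[1] == pytest.approx(10 ** (-5.3 - 5.2e-5 * 1e4) * df)

    def test_added_component_keeps_normalization(self, rng):
        cfg = DopplerConfig(n_freq=2**12, f_max_hz=2e5)
        p = np.zeros(2**12)
        p[0] = 1.0
        h = DopplerHistogram(np.linspace(0, 2e5, 2**12), p)
        h2 = add_biological_zero(h, rng, cfg)
        assert h2.power.sum() == pytest.approx(1.0, abs=1e-12)
        assert h2.power[0] < 1.0
        assert h2.power[1:].sum() > 0

    def test_normal_flow_contrast_shift_below_one_percent(self, fm_small):
        from melsci.skin_model import tilt_weights_to_mean

        w = tilt_weights_to_mean(np.ones(10), _model(np.ones(10)).top_speeds,
                                 1.0)
        m = _model(w, c=0.55)
        dist = fm_small.path_distribution(m)
        dcfg = fm_small.cfg.doppler
        bz = (dcfg.bz_offset_mean + np.log10(dcfg.bz_scale),
              dcfg.bz_slope_mean)
        k_no = fm_small._contrast_from_g1(fm_small.basis.g1_model(m, dist)).K
        k_bz = fm_small._contrast_from_g1(
            fm_small.basis.g1_model(m, dist, bz=bz)).K
        assert np.abs(k_bz / k_no - 1).max() < 0.01

    def test_bz_dominates_high_frequencies_of_static_tissue(self, rng):
        cfg = DopplerConfig(n_freq=2**12, f_max_hz=2e5)
        p = np.zeros(2**12)
        p[0] = 1.0
        h = add_biological_zero(DopplerHistogram(np.linspace(0, 2e5, 2**12), p),
                                rng, cfg)
        assert h.power[h.freq > 1e3].sum() > 0


def test_tau_basis_matches_gridded_single_shift():
    """ĝ1_k from the closed-form Si expression equals the cosine transform
    of the gridded component spectrum."""
    cfg = DopplerConfig(n_freq=2**13, f_max_hz=2e5, n_theta=2048)
    # stay well inside the grid's tau resolution (~1/(few*df))
    tau = np.geomspace(1e-7, 1e-3, 200)
    basis = TauBasis(tau, (2.0, 8.0), cfg, n_theta=2048)
    for k, s in enumerate((2.0, 8.0)):
        h = single_shift_histogram_uniform(s, cfg)
        g_grid = h.g1(tau)
        assert np.abs(basis.ghat[k] - g_grid).max() < 2e-3
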