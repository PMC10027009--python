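"""Photon transport, path-length tables, interpolation and absorption."""

import numpy as np
import pytest

from melsci.config import MCConfig
from melsci.photon_mc import (JointPathDistribution, PathLengthTable,
                              _transport_kernel, apply_absorption,
                              dermis_absorption, interpolate_pathlengths,
                              mua_blood, run_mc_grid, vessel_packing_factor)


def _run_kernel(n, t_epi, t_up, mus, seed=5, max_path=250.0, nbins=24,
                lo=0.01, hi=250.0):
    edges = np.geomspace(lo, hi, nbins + 1)
    log_e = np.log(edges)
    hist = np.zeros((nbins, nbins + 1, nbins + 1))
    out = _transport_kernel(n, t_epi, t_up, mus, 1.4, max_path, seed,
                            log_e, log_e, log_e, hist, False, 0.948, 1.0)
    return out, hist, edges


class TestTransport:
    def test_every_photon_is_detected_or_killed(self):
        (det, kill, *_), hist, _ = _run_kernel(30_000, 0.2, 0.2, 1.6)
        assert det + kill == 30_000
        assert hist.sum() == det
        assert np.all(hist >= 0)

    def test_dermis_visiting_photons_cross_epidermis_twice(self):
        # a photon that reached the dermis traversed the epidermis down and
        # up: its epidermis path is at least 2·t_epi (photons scattering
        # only within the epidermis can exit with arbitrarily short paths)
        t_epi = 0.3
        _, hist, edges = _run_kernel(20_000, t_epi, 0.2, 1.6)
        reached_dermis = hist[:, 1:, :].sum(axis=(1, 2)) \
            + hist[:, :1, 1:].sum(axis=(1, 2))
        occupied = np.nonzero(reached_dermis > 0)[0]
        assert edges[occupied.min() + 1] >= 2 * t_epi * 0.999

    def test_thick_epidermis_blocks_dermis_layers(self):
        _, hist, _ = _run_kernel(5_000, 60.0, 0.2, 1.6, max_path=2000.0,
                                 hi=2000.0)
        # all detected photons have exactly-zero dermis path (zero bins)
        assert hist[:, 1:, :].sum() == 0
        assert hist[:, :, 1:].sum() == 0
        assert hist[:, 0, 0].sum() > 0

    def test_similarity_rescaling_of_geometry_and_scattering(self):
        # same seed + geometry and mfp scaled by 1/2 => identical walks with
        # all path lengths halved: per-layer path sums scale exactly
        (d1, k1, s1, s2, s3), _, _ = _run_kernel(8_000, 0.2, 0.2, 1.6)
        (d2, k2, r1, r2, r3), _, _ = _run_kernel(8_000, 0.1, 0.1, 3.2,
                                                 max_path=125.0)
        assert (d1, k1) == (d2, k2)
        assert r1 == pytest.approx(s1 / 2, rel=1e-9)
        assert r2 == pytest.approx(s2 / 2, rel=1e-9)
        assert r3 == pytest.approx(s3 / 2, rel=1e-9)

    def test_fixed_seed_reproducibility(self):
        out1, h1, _ = _run_kernel(5_000, 0.2, 0.2, 1.6, seed=9)
        out2, h2, _ = _run_kernel(5_000, 0.2, 0.2, 1.6, seed=9)
        assert out1 == out2
        assert np.array_equal(h1, h2)

    def test_mean_detected_path_grows_as_scattering_drops(self, mc_table):
        reps = [mc_table.reps_epi, mc_table.reps_dermis, mc_table.reps_dermis]
        means = []
        for j in range(len(mc_table.grid_musp)):
            h = mc_table.counts[0, j]
            h = h / h.sum()
            total = (np.einsum("ijk,i->", h, reps[0])
                     + np.einsum("ijk,j->", h, reps[1])
                     + np.einsum("ijk,k->", h, reps[2]))
            means.append(total)
        assert np.all(np.diff(means) < 0)  # musp grid is increasing

    def test_diffuse_reflectance_matches_diffusion_approximation(self):
        # homogeneous medium (equal mua in all layers), musp/mua = 100
        musp, mua = 2.0, 0.02
        _, hist, edges = _run_kernel(60_000, 0.1, 0.2, musp, seed=21,
                                     max_path=400.0, nbins=48, hi=400.0)
        reps = np.sqrt(edges[:-1] * edges[1:])
        reps0 = np.concatenate([[0.0], reps])
        l_tot = (reps[:, None, None] + reps0[None, :, None]
                 + reps0[None, None, :])
        r_mc = float((hist * np.exp(-mua * l_tot)).sum() / 60_000)
        # Groenhuis/Farrell semi-infinite diffuse reflectance, n = 1.4
        a = musp / (musp + mua)
        A = 3.25
        r_diff = (a / 2) * np.exp(-np.sqrt(3 * (1 - a))) \
            * (1 + np.exp(-4 / 3 * A * np.sqrt(3 * (1 - a))))
        assert r_mc == pytest.approx(r_diff, rel=0.10)


class TestGridAndInterpolation:
    def test_grid_runs_and_histograms_normalize(self, mc_table):
        assert np.all(mc_table.n_detected + mc_table.n_killed
                      == mc_table.n_photons)
        d = interpolate_pathlengths(mc_table, 0.2, 1.0)
        assert d.hist.sum() == pytest.approx(1.0)

    def test_interpolation_identity_at_grid_node(self, mc_table):
        t0 = float(mc_table.grid_t_epi[1])
        m0 = float(mc_table.grid_musp[2])
        d = interpolate_pathlengths(mc_table, t0, m0)
        node = mc_table.counts[1, 2]
        assert np.allclose(d.hist, node / node.sum())

    def test_midpoint_query_averages_neighbors(self, mc_table):
        # grids are log-spaced; the log-midpoint mixes neighbors 50/50
        t_mid = float(np.sqrt(mc_table.grid_t_epi[0] * mc_table.grid_t_epi[1]))
        m0 = float(mc_table.grid_musp[0])
        d = interpolate_pathlengths(mc_table, t_mid, m0)
        h0 = mc_table.counts[0, 0] / mc_table.counts[0, 0].sum()
        h1 = mc_table.counts[1, 0] / mc_table.counts[1, 0].sum()
        assert np.allclose(d.hist, 0.5 * h0 + 0.5 * h1, atol=1e-12)

    def test_query_outside_grid_is_rejected(self, mc_table):
        with pytest.raises(ValueError):
            interpolate_pathlengths(mc_table, 5.0, 1.6)
        with pytest.raises(ValueError):
            interpolate_pathlengths(mc_table, 0.2, 0.01)

    def test_table_hdf5_round_trip(self, mc_table, tmp_path):
        p = tmp_path / "table.h5"
        mc_table.save(p)
        back = PathLengthTable.load(p)
        assert np.array_equal(back.counts, mc_table.counts)
        assert np.array_equal(back.grid_t_epi, mc_table.grid_t_epi)
        assert back.n_photons == mc_table.n_photons

    def test_too_few_photons_rejected(self):
        cfg = MCConfig(n_photons=5000)
        with pytest.raises(ValueError):
            run_mc_grid(cfg, 0)


class TestAbsorption:
    def _single_cell(self):
        hist = np.zeros((1, 3, 3))
        hist[0, 1, 2] = 1.0  # l2 = 1.0 mm, l3 = 2.0 mm
        reps_epi = np.array([0.5])
        reps_dermis = np.array([0.0, 1.0, 2.0])  # zero bin + two cells
        return JointPathDistribution(hist, reps_epi, reps_dermis)

    def test_zero_absorption_leaves_weights_unchanged(self, mc_table):
        d = interpolate_pathlengths(mc_table, 0.2, 1.6)
        out = apply_absorption(d, 0.0, 0.0, 0.0)
        assert np.array_equal(out.hist, d.hist)

    def test_single_cell_beer_lambert_factor(self):
        d = self._single_cell()
        out = apply_absorption(d, 0.1, 0.2, 0.3)
        # path lengths (0.5, 1.0, 2.0) mm: factor exp(-0.85) ≈ 0.4274
        assert out.hist[0, 1, 2] == pytest.approx(np.exp(-0.85))
        assert out.hist[0, 1, 2] == pytest.approx(0.4274, abs=2e-4)

    def test_opaque_epidermis_removes_all_weight(self, mc_table):
        d = interpolate_pathlengths(mc_table, 0.2, 1.6)
        out = apply_absorption(d, 1e6, 0.0, 0.0)
        assert out.weight_total < 1e-12

    def test_negative_mua_rejected(self):
        with pytest.raises(ValueError):
            apply_absorption(self._single_cell(), -0.1, 0.0, 0.0)


class TestDermisAbsorption:
    def test_bloodless_dermis_is_baseline(self):
        assert dermis_absorption(0.0, 0.5, 0.05) == pytest.approx(0.02)

    def test_infinitesimal_vessels_reach_homogeneous_limit(self):
        mb = mua_blood(0.5)
        assert vessel_packing_factor(1e-9, mb) == pytest.approx(1.0)
        mua = dermis_absorption(1.0, 0.5, 1e-9)
        assert mua == pytest.approx(0.01 * mb + 0.99 * 0.02, rel=1e-6)

    def test_packing_factor_decreases_with_vessel_size(self):
        mb = mua_blood(0.2)
        ds = np.geomspace(1e-4, 2.0, 40)
        cp = np.array([vessel_packing_factor(d, mb) for d in ds])
        assert np.all(np.diff(cp) < 0)
        assert np.all((cp > 0) & (cp <= 1))

    def test_out_of_range_saturation_rejected(self):
        with pytest.raises(ValueError):
            dermis_absorption(1.0, 1.5, 0.05)
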