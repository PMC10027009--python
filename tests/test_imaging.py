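"""Image containers, per-pixel prediction, fixtures and ROI statistics."""

import numpy as np
import pytest

from melsci.imaging import (ContrastImageStack, PerfusionImage, SceneRegion,
                            ScenePhase, color_scale, predict_image, roi_stats,
                            synth_image_fixture, temporal_smooth)
from melsci.perfusion_ann import AnnModel, predict


def _rand_model(rng):
    return AnnModel(W1=rng.normal(size=(7, 25)) * 0.3, b1=rng.normal(size=25),
                    W2=rng.normal(size=(25, 3)) * 0.3,
                    b2=np.array([0.1, 0.1, 0.1]),
                    x_mean=np.full(7, 0.5), x_std=np.full(7, 0.2))


def _rand_stack(rng, shape=(6, 8)):
    return ContrastImageStack(rng.uniform(0.2, 1.0, shape + (7,)))


class TestContainers:
    def test_stack_round_trip_is_lossless(self, rng, tmp_path):
        stack = _rand_stack(rng)
        stack.intensity = rng.random((6, 8)).astype(np.float32)
        stack.meta = {"seed": 4}
        p = tmp_path / "stack.h5"
        stack.save(p)
        back = ContrastImageStack.load(p)
        assert np.array_equal(back.contrast, stack.contrast)
        assert np.array_equal(back.intensity, stack.intensity)
        assert back.meta["seed"] == 4

    def test_perfusion_image_round_trip(self, rng, tmp_path):
        img = PerfusionImage(rng.normal(size=(6, 8, 3)).astype(np.float32))
        p = tmp_path / "perf.h5"
        img.save(p)
        back = PerfusionImage.load(p)
        assert np.array_equal(back.components, img.components)

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            ContrastImageStack(rng.random((6, 8, 5)))
        with pytest.raises(ValueError):
            ContrastImageStack(rng.random((6, 8, 7)),
                               exposures_ms=np.arange(7))

    def test_total_is_component_sum_and_render_clamps(self, rng):
        img = PerfusionImage(rng.normal(size=(4, 4, 3)))
        assert np.allclose(img.p_total, img.components.sum(-1))
        assert np.all(img.rendered("low") >= 0)
        # raw component keeps negatives
        if (img.components[..., 0] < 0).any():
            assert (img.component("low") < 0).any()


class TestPredictImage:
    def test_matches_per_pixel_loop_oracle(self, rng):
        model = _rand_model(rng)
        stack = _rand_stack(rng)
        img = predict_image(model, stack)
        for idx in [(0, 0), (3, 5), (5, 7)]:
            k2 = np.asarray(stack.contrast[idx], dtype=float) ** 2
            assert np.allclose(img.components[idx], predict(model, k2),
                               atol=1e-6)

    def test_constant_stack_gives_constant_maps(self, rng):
        model = _rand_model(rng)
        stack = ContrastImageStack(np.broadcast_to(
            np.linspace(0.9, 0.5, 7), (5, 5, 7)).copy())
        img = predict_image(model, stack)
        assert np.allclose(img.components, img.components[0, 0])

    def test_pixel_permutation_equivariance(self, rng):
        model = _rand_model(rng)
        stack = _rand_stack(rng)
        perm = rng.permutation(6)
        img = predict_image(model, stack)
        img_p = predict_image(model, ContrastImageStack(stack.contrast[perm]))
        assert np.allclose(img_p.components, img.components[perm])

    def test_time_resolved_stack_supported(self, rng):
        model = _rand_model(rng)
        stack = ContrastImageStack(rng.uniform(0.2, 1, (3, 4, 5, 7)))
        img = predict_image(model, stack)
        assert img.components.shape == (3, 4, 5, 3)


class TestSyntheticScene:
    def _regions(self):
        def strip(shape):
            m = np.zeros(shape, dtype=bool)
            m[shape[0] // 3, :] = True
            return m

        return [SceneRegion("background", {"mean_speed": 0.5, "c_blood": 0.4}),
                SceneRegion("vessel", {"mean_speed": 50.0, "c_blood": 2.0},
                            strip)]

    def test_fast_region_has_higher_p_high_and_lower_contrast(self, fm_small,
                                                              rng):
        stack, truth, _ = synth_image_fixture(fm_small, (6, 9),
                                              self._regions(), rng,
                                              noise=False)
        strip_row, bg_row = 2, 0
        assert truth.components[strip_row, 0, 2] > truth.components[bg_row, 0, 2]
        assert stack.contrast[strip_row, 0, -1] < stack.contrast[bg_row, 0, -1]

    def test_zero_noise_fixture_reproducible(self, fm_small):
        r1 = synth_image_fixture(fm_small, (4, 6), self._regions(),
                                 np.random.default_rng(5), noise=False)
        r2 = synth_image_fixture(fm_small, (4, 6), self._regions(),
                                 np.random.default_rng(5), noise=False)
        assert np.array_equal(r1[0].contrast, r2[0].contrast)
        assert np.array_equal(r1[1].components, r2[1].components)

    def test_occlusion_phase_makes_low_band_dominant(self, fm_small, rng):
        regions = [SceneRegion("background", {"mean_speed": 3.0,
                                              "c_blood": 0.8})]
        phases = [ScenePhase("baseline", 1),
                  ScenePhase("occlusion", 1, {"mean_speed": 0.29})]
        stack, truth, _ = synth_image_fixture(fm_small, (3, 4), regions, rng,
                                              phases=phases, noise=False)
        assert stack.contrast.ndim == 4
        occl = truth.components[1, 0, 0]
        assert occl[0] == max(occl)  # 0-1 mm/s band largest during occlusion
        base = truth.components[0, 0, 0]
        assert base[0] < base.sum() / 2

    def test_background_region_must_cover_frame(self, fm_small, rng):
        with pytest.raises(ValueError):
            synth_image_fixture(fm_small, (4, 4),
                                [SceneRegion("x", {}, lambda s: np.ones(s))],
                                rng)


class TestRoiStats:
    def test_two_pixel_example_population_sd(self):
        img = PerfusionImage(np.stack([np.array([[1.0, 3.0]])] * 3, axis=-1))
        mask = np.array([[True, True]])
        st = roi_stats(img, mask)
        assert st["low"]["mean"] == pytest.approx(2.0)
        assert st["low"]["sd"] == pytest.approx(1.0)  # population convention
        assert st["low"]["cv_pct"] == pytest.approx(50.0)
        assert st["total"]["mean"] == pytest.approx(6.0)

    def test_constant_image_zero_cv(self):
        img = PerfusionImage(np.full((3, 3, 3), 0.7))
        st = roi_stats(img, np.ones((3, 3), dtype=bool))
        for comp in st.values():
            assert comp["cv_pct"] == 0.0

    def test_cv_scale_invariance(self, rng):
        arr = rng.uniform(0.5, 2.0, (4, 4, 3))
        mask = np.ones((4, 4), dtype=bool)
        cv1 = roi_stats(PerfusionImage(arr), mask)["mid"]["cv_pct"]
        cv2 = roi_stats(PerfusionImage(3.7 * arr), mask)["mid"]["cv_pct"]
        assert cv1 == pytest.approx(cv2)

    def test_empty_mask_rejected(self, rng):
        img = PerfusionImage(rng.random((3, 3, 3)))
        with pytest.raises(ValueError):
            roi_stats(img, np.zeros((3, 3), dtype=bool))


class TestDisplayHelpers:
    def test_color_scale_three_times_roi_mean(self):
        img = PerfusionImage(np.full((2, 2, 3), 0.5 / 3))
        mask = np.ones((2, 2), dtype=bool)
        assert color_scale(img, mask, "total") == (0.0, 3 * 0.5)

    def test_color_scale_empty_mask_fallback(self, rng):
        img = PerfusionImage(rng.random((3, 3, 3)))
        lo, hi = color_scale(img, np.zeros((3, 3), dtype=bool), "low")
        assert hi == pytest.approx(3 * np.maximum(
            img.components[..., 0], 0).mean(), rel=1e-6)

    def test_temporal_smoothing_properties(self):
        const = np.full(20, 1.3)
        assert np.allclose(temporal_smooth(const, 0.5, 15.6), const)
        x = np.zeros(9)
        x[4] = 1.0
        sm = temporal_smooth(x, 3.0, 1.0)  # 3-sample window at 1 Hz
        assert np.allclose(sm[3:6], 1 / 3)
        assert sm[0] == 0.0
        # window of one sample is the identity
        assert np.allclose(temporal_smooth(x, 1.0, 1.0), x)
        with pytest.raises(ValueError):
            temporal_smooth(x, 0.1, 1.0)


def test_png_rendering_writes_file(rng, tmp_path):
    img = PerfusionImage(rng.uniform(0, 1, (6, 8, 3)).astype(np.float32))
    p = tmp_path / "map.png"
    img.save_png(p, "total", np.ones((6, 8), dtype=bool))
    assert p.exists() and p.stat().st_size > 500
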