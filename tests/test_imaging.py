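"""Rendering, luminance, warping, and ensemble-capture unit tests."""

import numpy as np
import pytest

from retinastats import (
    GazeSpec,
    HUMAN_EYE,
    ImagePatch,
    PatchEnsemble,
    VisualFieldCoord,
    capture_ensemble,
    homography_for,
    normalize_mean,
    render_patch,
    to_luminance,
    warp_to_tangent,
)
from retinastats.geometry import pixel_pitch_mm
from retinastats.imaging import max_valid_warp_size, render_full_frame
from retinastats.scene import Pose, build_smooth_scene, generate_trajectory

SCENE = build_smooth_scene(0)
POSE = Pose(np.array([0.0, HUMAN_EYE.eye_height_m, 0.0]), 0.0, 0)
VIEW = (0.0, 0.0)


def make_patch(arr, projection="planar", coord=VisualFieldCoord(0.0)):
    return ImagePatch(np.asarray(arr, float), 0.01, projection, coord)


class TestLuminance:
    def test_white_maps_to_one(self):
        p = make_patch(np.ones((16, 16, 3)))
        np.testing.assert_allclose(to_luminance(p).pixels, 1.0)

    def test_gray_maps_to_itself(self):
        p = make_patch(np.full((16, 16, 3), 0.3))
        np.testing.assert_allclose(to_luminance(p).pixels, 0.3, atol=1e-12)

    def test_green_brighter_than_red(self):
        red = np.zeros((16, 16, 3)); red[..., 0] = 1.0
        green = np.zeros((16, 16, 3)); green[..., 1] = 1.0
        yr = to_luminance(make_patch(red)).pixels[0, 0]
        yg = to_luminance(make_patch(green)).pixels[0, 0]
        assert yg > yr > 0

    def test_rejects_grayscale_input(self):
        with pytest.raises(ValueError):
            to_luminance(make_patch(np.ones((16, 16))))

    def test_out_of_range_warns_and_clamps(self):
        arr = np.full((16, 16, 3), 1.5)
        with pytest.warns(UserWarning):
            out = to_luminance(make_patch(arr))
        assert out.pixels.max() <= 1.0 + 1e-9


class TestNormalizeMean:
    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        p = make_patch(rng.uniform(0.1, 1.0, (32, 32)))
        assert normalize_mean(p).pixels.mean() == pytest.approx(1.0)

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0.1, 1.0, (32, 32))
        n1 = normalize_mean(make_patch(arr)).pixels
        n2 = normalize_mean(make_patch(7.3 * arr)).pixels
        n3 = normalize_mean(make_patch(n1)).pixels
        np.testing.assert_allclose(n1, n2, atol=1e-12)
        np.testing.assert_allclose(n1, n3, atol=1e-12)

    def test_zero_patch_raises(self):
        with pytest.raises(ValueError):
            normalize_mean(make_patch(np.zeros((32, 32))))


class TestRendering:
    def test_deterministic(self):
        c = VisualFieldCoord(30, 45)
        a = render_patch(SCENE, POSE, VIEW, c, HUMAN_EYE, 256, patch_px=24)
        b = render_patch(SCENE, POSE, VIEW, c, HUMAN_EYE, 256, patch_px=24)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_center_patch_equals_central_crop_of_full_frame(self):
        res = 64
        full = render_full_frame(SCENE, POSE, VIEW, HUMAN_EYE, res)
        patch = render_patch(
            SCENE, POSE, VIEW, VisualFieldCoord(0.0), HUMAN_EYE, res, patch_px=16
        )
        o = (res - 16) // 2
        np.testing.assert_allclose(
            patch.pixels, full.pixels[o : o + 16, o : o + 16], atol=1e-12
        )

    def test_pitch_inherited_from_frame(self):
        p = render_patch(
            SCENE, POSE, VIEW, VisualFieldCoord(0.0), HUMAN_EYE, 512, patch_px=8
        )
        assert p.pixel_pitch_mm == pytest.approx(pixel_pitch_mm(HUMAN_EYE, 512, 120.0))


class TestWarping:
    def test_identity_at_center(self):
        c = VisualFieldCoord(0.0)
        p = render_patch(SCENE, POSE, VIEW, c, HUMAN_EYE, 256, patch_px=48)
        p = to_luminance(p)
        h = homography_for(c, HUMAN_EYE, p.pixel_pitch_mm)
        w = warp_to_tangent(p, h, 32)
        o = (48 - 32) // 2
        np.testing.assert_allclose(
            w.pixels, p.pixels[o : o + 32, o : o + 32], atol=1e-9
        )
        assert w.projection == "tangent"
        assert w.valid.all()

    def test_oversized_output_raises_with_max_size(self):
        c = VisualFieldCoord(50, 45)
        pitch = pixel_pitch_mm(HUMAN_EYE, 1024, 120.0)
        h = homography_for(c, HUMAN_EYE, pitch)
        p = render_patch(SCENE, POSE, VIEW, c, HUMAN_EYE, 1024, patch_px=64)
        p = to_luminance(p)
        limit = max_valid_warp_size(h, 64)
        with pytest.raises(ValueError):
            warp_to_tangent(p, h, limit + 8)
        w = warp_to_tangent(p, h, limit)
        assert w.patch_px == limit

    def test_rejects_tangent_input(self):
        c = VisualFieldCoord(30, 0)
        pitch = pixel_pitch_mm(HUMAN_EYE, 1024, 120.0)
        h = homography_for(c, HUMAN_EYE, pitch)
        p = make_patch(np.ones((64, 64)), projection="tangent", coord=c)
        with pytest.raises(ValueError):
            warp_to_tangent(p, h, 16)


class TestCaptureEnsemble:
    def test_counts_and_manifest(self):
        poses = generate_trajectory(0, 3, HUMAN_EYE)
        grid = [VisualFieldCoord(0.0), VisualFieldCoord(20, 0), VisualFieldCoord(20, 180)]
        ens = capture_ensemble(
            SCENE, poses, GazeSpec("straight"), HUMAN_EYE, grid, 256, patch_px=24
        )
        assert len(ens) == 9
        assert set(ens.manifest.projection) == {"planar"}
        assert sorted(set(ens.manifest.phi_deg)) == [0.0, 20.0]

    def test_tangent_twins(self):
        poses = generate_trajectory(0, 2, HUMAN_EYE)
        grid = [VisualFieldCoord(20, 90)]
        ens = capture_ensemble(
            SCENE, poses, GazeSpec("straight"), HUMAN_EYE, grid, 256,
            patch_px=96, tangent_out_px=24,
        )
        assert len(ens) == 4
        assert len(ens.select(projection="tangent")) == 2

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            capture_ensemble(
                SCENE, generate_trajectory(0, 1, HUMAN_EYE), GazeSpec("straight"),
                HUMAN_EYE, [], 256,
            )

    def test_concatenate(self):
        poses = generate_trajectory(0, 2, HUMAN_EYE)
        grid = [VisualFieldCoord(0.0)]
        e1 = capture_ensemble(
            SCENE, poses, GazeSpec("straight"), HUMAN_EYE, grid, 256, patch_px=24
        )
        both = PatchEnsemble.concatenate([e1, e1])
        assert len(both) == 2 * len(e1)
        assert len(both.manifest) == 2 * len(e1.manifest)
        with pytest.raises(ValueError):
            PatchEnsemble.concatenate([])
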