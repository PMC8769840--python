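"""Scale-space construction, DoG extrema, orientations and descriptors."""

import numpy as np
import pytest
from scipy import ndimage

from wbckit.sift import (
    SIFTConfig,
    KeyPoint,
    assign_orientation,
    build_dog,
    build_scale_space,
    compute_descriptor,
    detect_extrema,
    extract,
    to_grayscale,
)


class TestScaleSpace:
    def test_constant_image_stays_constant(self):
        ss = build_scale_space(np.full((32, 32), 0.7))
        for stack in ss.octaves:
            np.testing.assert_allclose(stack, 0.7, atol=1e-12)

    def test_sigmas_strictly_increase(self):
        ss = build_scale_space(np.zeros((32, 32)), n_levels=6)
        assert np.all(np.diff(ss.sigmas) > 0)
        assert len(ss.sigmas) >= 4

    def test_impulse_becomes_gaussian(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        ss = build_scale_space(img, n_octaves=1, sigma0=1.6, assumed_blur=0.0)
        for level, sigma in zip(ss.octaves[0], ss.sigmas):
            assert level.sum() == pytest.approx(1.0, abs=1e-3)
            yy, xx = np.mgrid[0:64, 0:64]
            expected = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * sigma**2))
            expected /= expected.sum()
            assert np.abs(level - expected).max() < 1e-3

    def test_incremental_blurs_compose_like_direct_blurs(self, rng):
        # semigroup property: the chain of incremental blurs that
        # builds each level must equal one direct blur from the base
        img = rng.random((40, 40))
        ss = build_scale_space(img, n_octaves=1, assumed_blur=1.6)
        for level, sigma in zip(ss.octaves[0][1:], ss.sigmas[1:]):
            direct = ndimage.gaussian_filter(
                img, np.sqrt(sigma**2 - ss.sigmas[0] ** 2), truncate=6.0
            )
            assert np.abs(level - direct).max() < 1e-6

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(np.zeros((10, 10)))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(np.zeros((32, 32)), n_levels=3)


class TestDoG:
    def test_constant_image_gives_zero_dog(self):
        ss = build_scale_space(np.full((32, 32), 0.4))
        for stack in build_dog(ss):
            np.testing.assert_allclose(stack, 0.0, atol=1e-12)

    def test_elementwise_subtraction(self, rng):
        ss = build_scale_space(rng.random((32, 32)))
        dog = build_dog(ss)
        for o, stack in enumerate(dog):
            assert stack.shape[0] == ss.octaves[o].shape[0] - 1
            for i in range(stack.shape[0]):
                for r in range(0, stack.shape[1], 7):
                    for c in range(0, stack.shape[2], 7):
                        assert stack[i, r, c] == pytest.approx(
                            ss.octaves[o][i + 1, r, c] - ss.octaves[o][i, r, c]
                        )

    def test_linear_ramp_has_vanishing_interior_dog(self):
        # Gaussian smoothing preserves linear functions away from the
        # image boundary, so interior DoG responses vanish
        img = np.linspace(0, 1, 160)[None, :] * np.ones((160, 1))
        ss = build_scale_space(img, n_octaves=1)
        dog = build_dog(ss)[0]
        interior = dog[:, 40:-40, 40:-40]
        assert np.abs(interior).max() < 1e-6


def brute_extrema(D):
    """Triple-loop strict 26-neighbor extremum scan (interior only)."""
    L, H, W = D.shape
    found = []
    for i in range(1, L - 1):
        for r in range(1, H - 1):
            for c in range(1, W - 1):
                v = D[i, r, c]
                neigh = [
                    D[i + di, r + dr, c + dc]
                    for di in (-1, 0, 1)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (di, dr, dc) != (0, 0, 0)
                ]
                if v > max(neigh) or v < min(neigh):
                    found.append((i, r, c))
    return set(found)


class TestDetectExtrema:
    def test_constant_image_yields_no_keypoints(self):
        ss = build_scale_space(np.full((32, 32), 0.5))
        assert detect_extrema(build_dog(ss)) == []

    def test_blob_keypoint_near_center(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((yy - 30) ** 2 + (xx - 34) ** 2) / (2 * 4.0**2))
        ss = build_scale_space(img)
        kps = detect_extrema(build_dog(ss), sigmas=ss.sigmas)
        assert kps
        d = min(np.hypot(kp.x - 34, kp.y - 30) for kp in kps)
        assert d <= 2.0

    def test_strictness_against_brute_force(self, rng):
        D = rng.normal(size=(4, 10, 10))
        expected = brute_extrema(D)
        kps = detect_extrema([D], contrast_threshold=0.0, edge_ratio=1e12)
        got = {(kp.scale_index, int(round(kp.y)), int(round(kp.x))) for kp in kps}
        # every reported point is a strict brute-force extremum
        assert got <= expected
        # every brute-force extremum passing the curvature screen is reported
        for i, r, c in expected:
            dxx = D[i, r, c + 1] + D[i, r, c - 1] - 2 * D[i, r, c]
            dyy = D[i, r + 1, c] + D[i, r - 1, c] - 2 * D[i, r, c]
            dxy = 0.25 * (
                D[i, r + 1, c + 1] - D[i, r + 1, c - 1]
                - D[i, r - 1, c + 1] + D[i, r - 1, c - 1]
            )
            if dxx * dyy - dxy**2 > 0:
                assert (i, r, c) in got

    def test_too_few_levels_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_extrema([rng.normal(size=(2, 8, 8))])


def step_edge_image():
    img = np.zeros((48, 48))
    img[24:, :] = 1.0
    return ndimage.gaussian_filter(img, 1.0)


class TestOrientation:
    def test_step_edge_orientation_is_gradient_normal(self):
        ss = build_scale_space(step_edge_image(), n_octaves=1)
        kp = KeyPoint(x=24.0, y=24.0, octave=0, scale_index=1, sigma=2.0)
        oriented = assign_orientation(kp, ss)
        # intensity increases downward -> gradient points to +y (pi/2)
        bin_width = 2 * np.pi / 36
        assert abs(oriented.orientation - np.pi / 2) <= bin_width

    def test_rotating_image_rotates_orientation(self):
        img = step_edge_image()
        ss = build_scale_space(img, n_octaves=1)
        ss_rot = build_scale_space(np.rot90(img, k=-1), n_octaves=1)
        kp = KeyPoint(x=24.0, y=24.0, octave=0, scale_index=1, sigma=2.0)
        a = assign_orientation(kp, ss).orientation
        b = assign_orientation(kp, ss_rot).orientation
        bin_width = 2 * np.pi / 36
        diff = np.mod(b - a + np.pi, 2 * np.pi) - np.pi
        assert abs(abs(diff) - np.pi / 2) <= bin_width

    def test_flat_window_defaults_to_zero(self):
        ss = build_scale_space(np.full((32, 32), 0.3), n_octaves=1)
        kp = KeyPoint(x=16.0, y=16.0, octave=0, scale_index=1, sigma=2.0)
        assert assign_orientation(kp, ss).orientation == 0.0


class TestDescriptor:
    def make_blob_ss(self, size=96, sigma_blob=4.0):
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.exp(
            -((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (2 * sigma_blob**2)
        )
        return build_scale_space(img)

    def test_descriptor_is_unit_128_nonnegative(self):
        ss = self.make_blob_ss()
        kps = detect_extrema(build_dog(ss), sigmas=ss.sigmas)
        assert kps
        kp = assign_orientation(kps[0], ss)
        desc = compute_descriptor(kp, ss)
        assert desc is not None
        assert desc.shape == (128,)
        assert np.all(desc >= 0)
        assert np.linalg.norm(desc) == pytest.approx(1.0, abs=1e-9)

    def test_flat_window_is_dropped(self):
        ss = build_scale_space(np.full((64, 64), 0.5), n_octaves=1)
        kp = KeyPoint(x=32.0, y=32.0, octave=0, scale_index=1, sigma=2.0)
        assert compute_descriptor(kp, ss) is None

    def test_out_of_bounds_window_is_dropped(self):
        ss = self.make_blob_ss()
        kp = KeyPoint(x=1.0, y=1.0, octave=0, scale_index=1, sigma=2.0)
        assert compute_descriptor(kp, ss) is None

    def test_scale_doubling_preserves_descriptor(self, blob_image):
        pairs = extract(blob_image)
        doubled = ndimage.zoom(blob_image, 2, order=1)
        pairs2 = extract(doubled)
        matched = 0
        close = 0
        for kp, d in pairs:
            best = min(
                pairs2, key=lambda p: np.hypot(p[0].x - 2 * kp.x, p[0].y - 2 * kp.y)
            )
            if np.hypot(best[0].x - 2 * kp.x, best[0].y - 2 * kp.y) <= 4:
                matched += 1
                if np.linalg.norm(d - best[1]) <= 0.3:
                    close += 1
        assert matched >= len(pairs) / 2
        assert close >= matched / 2


class TestExtract:
    def test_constant_image_gives_empty_list(self):
        assert extract(np.full((48, 48), 0.6)) == []

    def test_deterministic(self, blob_image):
        a = extract(blob_image)
        b = extract(blob_image)
        assert len(a) == len(b)
        for (kp1, d1), (kp2, d2) in zip(a, b):
            assert (kp1.x, kp1.y, kp1.sigma, kp1.orientation) == (
                kp2.x, kp2.y, kp2.sigma, kp2.orientation,
            )
            np.testing.assert_array_equal(d1, d2)

    def test_finds_every_planted_blob(self, blob_image, blob_centers):
        pairs = extract(blob_image)
        for cy, cx in blob_centers:
            assert any(np.hypot(kp.x - cx, kp.y - cy) <= 2 for kp, _ in pairs)

    def test_rgb_input_converted_by_luminance(self, blob_image):
        rgb = np.stack([blob_image] * 3, axis=-1)
        gray_pairs = extract(blob_image)
        rgb_pairs = extract(rgb)
        assert len(gray_pairs) == len(rgb_pairs)

    def test_rotation_invariance_of_descriptors(self, blob_image):
        pairs = extract(blob_image)
        rot = extract(np.rot90(blob_image, k=-1))
        h = blob_image.shape[0]
        matched, close = 0, 0
        for kp, d in pairs:
            rx, ry = h - 1 - kp.y, kp.x
            best = min(rot, key=lambda p: np.hypot(p[0].x - rx, p[0].y - ry))
            if np.hypot(best[0].x - rx, best[0].y - ry) <= 3:
                matched += 1
                if np.linalg.norm(d - best[1]) <= 0.3:
                    close += 1
        assert matched > 0
        assert close >= 0.8 * matched

    def test_half_of_keypoints_match_established_implementation(self, rng):
        from skimage.feature import SIFT as SkimageSIFT

        yy, xx = np.mgrid[0:160, 0:160]
        img = np.zeros((160, 160))
        for _ in range(8):
            y, x = rng.uniform(25, 135, 2)
            s = rng.uniform(2.5, 6)
            a = rng.uniform(0.5, 1.0) * rng.choice([-1, 1])
            img += a * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * s * s))
        img = (img - img.min()) / (img.max() - img.min())
        ours = extract(img)
        assert ours
        det = SkimageSIFT()
        det.detect_and_extract(img)
        ref = det.keypoints
        matched = sum(
            1
            for kp, _ in ours
            if ((ref[:, 0] - kp.y) ** 2 + (ref[:, 1] - kp.x) ** 2).min() <= 9
        )
        assert matched >= 0.5 * len(ours)


def test_grayscale_conversion_weights():
    rgb = np.zeros((2, 2, 3))
    rgb[..., 1] = 255.0
    gray = to_grayscale(rgb)
    assert gray[0, 0] == pytest.approx(0.587)
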