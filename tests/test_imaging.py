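"""Backprojection reconstruction against a brute-force oracle, localization,
symmetry, normalization and rendering."""

import numpy as np
import pytest

import beltscan as bs
from beltscan.errors import ValidationError
from beltscan.imaging import (
    PixelGrid,
    ReconstructedImage,
    normalize_to_reference,
    reconstruct_image,
    render_image,
    resize_raster,
    save_png,
)
from beltscan.phantom import make_belt
from beltscan.types import C0
from conftest import make_tumor_scenario


def brute_force_image(sweep, belt, pixels, eps_r):
    """Independent oracle: direct triple loop over pixels, pairs, freqs."""
    k = 2 * np.pi * sweep.grid.frequencies * np.sqrt(eps_r) / C0
    out = np.zeros((pixels.ny, pixels.nx))
    for iy, y in enumerate(pixels.y_centers):
        for ix, x in enumerate(pixels.x_centers):
            acc = 0.0 + 0.0j
            for i in range(belt.n_antennas):
                di = np.hypot(x - belt.positions[i, 0], y - belt.positions[i, 1])
                for j in range(belt.n_antennas):
                    dj = np.hypot(x - belt.positions[j, 0],
                                  y - belt.positions[j, 1])
                    for q in range(sweep.grid.n_points):
                        acc += sweep.values[q, i, j] * np.exp(1j * k[q] * (di + dj))
            out[iy, ix] = abs(acc)
    return out


class TestReconstruction:
    def test_matches_brute_force_oracle_on_a_small_instance(self, rng):
        grid = bs.FrequencyGrid(1.0e9, 2.0e9, 5)
        pos = np.array([[0.1, 0.0, 0.0], [-0.07, 0.05, 0.0]])
        belt = bs.AntennaBelt(pos)
        v = rng.normal(size=(5, 2, 2)) + 1j * rng.normal(size=(5, 2, 2))
        v = 0.5 * (v + np.swapaxes(v, 1, 2))
        sweep = bs.SMatrixSweep(grid, v, bs.SweepKind.CALIBRATED)
        pixels = PixelGrid(16, 16, (-0.12, 0.12, -0.12, 0.12))
        bg = bs.TissueDielectric(eps_r=35.0, sigma=0.0)
        img = reconstruct_image(sweep, belt, pixels, bg)
        oracle = brute_force_image(sweep, belt, pixels, 35.0)
        np.testing.assert_allclose(img.intensity, oracle, rtol=1e-9)

    def test_zero_sweep_gives_zero_image(self, belt8, grid64):
        sweep = bs.SMatrixSweep(grid64, np.zeros((64, 8, 8), complex))
        img = reconstruct_image(sweep, belt8, PixelGrid(16, 16))
        assert np.all(img.intensity == 0)

    def test_intensity_is_homogeneous_in_the_sweep(self, comp20, belt8):
        cal = bs.calibrate(comp20.body, comp20.empty)
        img1 = reconstruct_image(cal, belt8, PixelGrid(16, 16))
        scaled = bs.SMatrixSweep(cal.grid, 3.0 * cal.values, cal.kind)
        img3 = reconstruct_image(scaled, belt8, PixelGrid(16, 16))
        np.testing.assert_allclose(img3.intensity, 3.0 * img1.intensity, rtol=1e-9)

    def test_point_scatterer_localized_within_one_pixel(
        self, lossless_background, rng
    ):
        """Across 20 seeded positions the argmax is within one pixel."""
        grid = bs.FrequencyGrid(0.5e9, 3.5e9, 120)
        pixels = PixelGrid(48, 48)
        px = (pixels.extent[1] - pixels.extent[0]) / pixels.nx
        py = (pixels.extent[3] - pixels.extent[2]) / pixels.ny
        for _ in range(20):
            side = rng.choice([-1, 1])
            r = 0.03 * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            center = (side * 0.06 + r * np.cos(th), r * np.sin(th), 0.0)
            scen = make_tumor_scenario(
                6.0, center=center,
                background_tissue=lossless_background, skin_amplitude=0.0,
            )
            belt = make_belt(scen)
            body, empty = bs.simulate_sweep(scen, grid=grid)
            img = reconstruct_image(bs.calibrate(body, empty), belt, pixels,
                                    lossless_background)
            mx, my = img.argmax_xy()
            assert abs(mx - center[0]) <= px + 1e-12
            assert abs(my - center[1]) <= py + 1e-12

    def test_mirrored_scenario_gives_mirrored_image(self, grid64):
        def image_for(x0):
            scen = make_tumor_scenario(20.0, center=(x0, 0.013, 0.0))
            belt = make_belt(scen)
            body, empty = bs.simulate_sweep(scen, grid=grid64)
            # components only: clutter is seed-dependent and cancels anyway
            return reconstruct_image(bs.preprocess_case(body, empty), belt,
                                     PixelGrid(32, 32, (-0.16, 0.16, -0.11, 0.11)))

        left = image_for(-0.06)
        right = image_for(+0.06)
        np.testing.assert_allclose(
            left.intensity, np.flip(right.intensity, axis=1), rtol=1e-9
        )

    def test_grid_must_enclose_the_belt(self, comp20, belt8):
        cal = bs.calibrate(comp20.body, comp20.empty)
        with pytest.raises(ValidationError):
            reconstruct_image(cal, belt8, PixelGrid(8, 8, (-0.01, 0.01, -0.01, 0.01)))


class TestNormalization:
    def test_self_normalized_peak_is_one(self, comp20, belt8):
        img = reconstruct_image(bs.calibrate(comp20.body, comp20.empty), belt8,
                                PixelGrid(16, 16))
        normed = normalize_to_reference(img, img.peak)
        assert normed.normalized.max() == pytest.approx(1.0)

    def test_doubling_the_reference_halves_the_values(self, comp20, belt8):
        img = reconstruct_image(bs.calibrate(comp20.body, comp20.empty), belt8,
                                PixelGrid(16, 16))
        n1 = normalize_to_reference(img, 2.0)
        n2 = normalize_to_reference(img, 4.0)
        np.testing.assert_allclose(n2.normalized, n1.normalized / 2)

    def test_non_positive_reference_rejected(self, comp20, belt8):
        img = reconstruct_image(bs.calibrate(comp20.body, comp20.empty), belt8,
                                PixelGrid(16, 16))
        with pytest.raises(ValidationError):
            normalize_to_reference(img, 0.0)

    def test_normalized_peak_increases_with_diameter(self, grid64):
        """Image response ordering for 8 < 20 < 36 < 48 mm tumors."""
        scen0 = bs.TorsoScenario()
        belt = make_belt(scen0)
        body0, empty0 = bs.simulate_sweep(scen0, grid=grid64)
        ref = reconstruct_image(bs.calibrate(body0, empty0), belt,
                                PixelGrid(32, 32)).peak
        peaks = []
        for d in (8.0, 20.0, 36.0, 48.0):
            scen = make_tumor_scenario(d)
            body, empty = bs.simulate_sweep(scen, grid=grid64)
            img = reconstruct_image(bs.preprocess_case(body, empty), belt,
                                    PixelGrid(32, 32))
            peaks.append(normalize_to_reference(img, ref).normalized.max())
        assert all(a < b for a, b in zip(peaks, peaks[1:]))


class TestRendering:
    @pytest.fixture()
    def image(self, comp20, belt8):
        img = reconstruct_image(bs.calibrate(comp20.body, comp20.empty), belt8,
                                PixelGrid(16, 16))
        return normalize_to_reference(img, img.peak)

    def test_constant_image_renders_to_constant_raster(self):
        grid = PixelGrid(8, 8)
        img = ReconstructedImage(grid, np.full((8, 8), 2.5), 1.0)
        raster = render_image(img, size=(32, 32))
        assert raster.shape == (32, 32, 3)
        assert np.all(raster == raster[0, 0])

    def test_rendering_is_deterministic(self, image, tmp_path):
        p1 = save_png(render_image(image), tmp_path / "a.png")
        p2 = save_png(render_image(image), tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_default_render_and_cnn_resize_shapes(self, image):
        raster = render_image(image)
        assert raster.shape == (496, 634, 3)  # (height, width, 3) for 634x496
        resized = resize_raster(raster, (400, 400))
        assert resized.shape == (400, 400, 3)

    def test_zero_size_raster_rejected(self, image):
        with pytest.raises(ValidationError):
            render_image(image, size=(0, 10))
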