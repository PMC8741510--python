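import numpy as np
import pytest
from scipy.spatial import Delaunay

from compeye.exceptions import EmptyMapError, NoLatticeError
from compeye.ommatidia import (OmmatidiaDetector, detect_centers,
                               find_fundamentals, reciprocal_image)
from compeye.synthetic import make_lattice_image

HEX_RADIUS_20 = 2.0 / (np.sqrt(3.0) * 20.0)  # ~0.0577 cycles/px


class TestReciprocalImage:
    def test_sinusoid_gives_symmetric_peak_pair(self):
        x = np.arange(200)
        img = np.tile(np.sin(2 * np.pi * x / 20.0), (200, 1))
        spec = reciprocal_image(img)
        peak = np.unravel_index(np.argmax(spec), spec.shape)
        fx = (peak[1] - 100) / 200.0
        assert abs(fx) == pytest.approx(1 / 20.0, abs=0.003)
        mirror = spec[2 * 100 - peak[0], 2 * 100 - peak[1]]
        assert mirror == pytest.approx(spec[peak], rel=0.05)

    def test_constant_image_rejected(self):
        with pytest.raises(NoLatticeError):
            reciprocal_image(np.full((64, 64), 3.0))

    def test_hex_lattice_first_order_ring(self):
        lat = make_lattice_image(spacing=20, n_spots=500, seed=0)
        spec = reciprocal_image(lat["image"], lat["mask"])
        fund = find_fundamentals(spec)
        radii = np.hypot(fund[:, 0], fund[:, 1])
        assert len(fund) == 6
        assert radii.mean() == pytest.approx(HEX_RADIUS_20, rel=0.03)
        # peaks 60 degrees apart
        ang = np.sort(np.degrees(np.arctan2(fund[:, 0], fund[:, 1])) % 360)
        gaps = np.diff(ang)
        assert np.allclose(gaps, 60.0, atol=6.0)


class TestFindFundamentals:
    def test_square_lattice_four_peaks(self):
        lat = make_lattice_image(spacing=20, n_spots=400, lattice="square",
                                 seed=1)
        fund = find_fundamentals(reciprocal_image(lat["image"], lat["mask"]))
        assert len(fund) == 4
        assert np.hypot(fund[:, 0], fund[:, 1]).mean() == pytest.approx(
            0.05, rel=0.03)

    @pytest.mark.parametrize("seed", range(20))
    def test_white_noise_rejected(self, seed):
        img = np.random.default_rng(seed).normal(size=(256, 256))
        with pytest.raises(NoLatticeError):
            find_fundamentals(reciprocal_image(img))

    def test_peaks_come_in_plus_minus_pairs(self):
        lat = make_lattice_image(spacing=16, n_spots=400, seed=2)
        fund = find_fundamentals(reciprocal_image(lat["image"], lat["mask"]))
        for p in fund:
            d = np.hypot(fund[:, 0] + p[0], fund[:, 1] + p[1]).min()
            assert d < 0.25 * np.hypot(*p)


class TestDetectCenters:
    def test_count_and_diameter_on_perfect_lattice(self):
        lat = make_lattice_image(spacing=20, n_spots=500, seed=3)
        det = OmmatidiaDetector(pixel_scale=1.0).fit(lat["image"], lat["mask"])
        assert abs(det.count_ - 500) / 500 <= 0.02
        assert det.facet_diameter_ == pytest.approx(20.0, rel=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_count_under_noise_snr5(self, seed):
        lat = make_lattice_image(spacing=20, n_spots=500, noise_sd=0.2,
                                 seed=seed)
        det = OmmatidiaDetector().fit(lat["image"], lat["mask"])
        assert abs(det.count_ - 500) / 500 <= 0.05

    def test_fewer_facets_than_n_center_warns_and_uses_all(self):
        lat = make_lattice_image(spacing=20, n_spots=200, seed=4)
        omap = OmmatidiaDetector(n_center=300).fit_predict(lat["image"],
                                                           lat["mask"])
        assert omap.warnings
        assert omap.count == pytest.approx(200, abs=4)

    def test_all_centers_inside_mask(self):
        lat = make_lattice_image(spacing=18, n_spots=300, seed=5)
        omap = OmmatidiaDetector().fit_predict(lat["image"], lat["mask"])
        ridx = np.round(omap.centers).astype(int)
        assert lat["mask"][ridx[:, 0], ridx[:, 1]].all()

    def test_empty_map_on_blank_lowpass(self):
        lat = make_lattice_image(spacing=20, n_spots=300, seed=6)
        fund = find_fundamentals(reciprocal_image(lat["image"], lat["mask"]))
        empty_mask = np.zeros_like(lat["mask"])
        with pytest.raises(EmptyMapError):
            detect_centers(lat["image"], empty_mask, fund)


class TestLatticeProperties:
    @pytest.mark.parametrize("spacing,seed", [(10, 0), (10, 1), (17, 2),
                                              (17, 3), (25, 4), (25, 5),
                                              (33, 6), (33, 7), (40, 8),
                                              (40, 9)])
    def test_spacing_linear_in_truth(self, spacing, seed):
        lat = make_lattice_image(spacing=spacing, n_spots=300, seed=seed)
        det = OmmatidiaDetector().fit(lat["image"], lat["mask"])
        assert det.lattice_spacing_px_ == pytest.approx(spacing, rel=0.05)
        assert abs(det.count_ - lat["count"]) / lat["count"] <= 0.05

    def test_intensity_scaling_invariance(self):
        lat = make_lattice_image(spacing=20, n_spots=300, seed=10)
        d1 = OmmatidiaDetector().fit(lat["image"], lat["mask"])
        d2 = OmmatidiaDetector().fit(5.0 * lat["image"] + 2.0, lat["mask"])
        assert d1.count_ == d2.count_
        assert d1.lattice_spacing_px_ == pytest.approx(
            d2.lattice_spacing_px_, rel=1e-6)

    def test_rotation_by_90_degrees(self):
        lat = make_lattice_image(spacing=20, n_spots=300, seed=11)
        d1 = OmmatidiaDetector().fit(lat["image"], lat["mask"])
        d2 = OmmatidiaDetector().fit(np.rot90(lat["image"]),
                                     np.rot90(lat["mask"]))
        assert abs(d2.count_ - d1.count_) / d1.count_ <= 0.02
        assert d2.lattice_spacing_px_ == pytest.approx(
            d1.lattice_spacing_px_, rel=0.01)

    def test_modal_delaunay_valence_is_six(self):
        lat = make_lattice_image(spacing=20, n_spots=400, seed=12)
        omap = OmmatidiaDetector().fit_predict(lat["image"], lat["mask"])
        tri = Delaunay(omap.centers)
        indptr, _ = tri.vertex_neighbor_vertices
        valence = np.diff(indptr)
        # interior points only (hull points have clipped neighborhoods)
        hull = set(tri.convex_hull.ravel())
        interior = np.array([v for i, v in enumerate(valence)
                             if i not in hull])
        values, counts = np.unique(interior, return_counts=True)
        assert values[counts.argmax()] == 6

    def test_detector_on_rendered_eye_composite(self, eye_stack_default,
                                                eye_surface_default):
        truth = eye_stack_default["truth"]
        det = OmmatidiaDetector(n_center=300).fit(
            eye_surface_default.composite, eye_surface_default.mask)
        assert det.lattice_spacing_px_ == pytest.approx(
            truth["lattice_spacing_px"], rel=0.05)
        assert det.count_ == pytest.approx(truth["facet_count"], rel=0.15)
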