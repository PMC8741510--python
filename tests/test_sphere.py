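import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compeye.exceptions import DegenerateGeometryError, InsufficientDataError
from compeye.sphere import (BeadCalibration, SphereFit, fit_sphere,
                            measure_fov, spherical_project)
from conftest import sphere_points


class TestFitSphere:
    def test_exact_unit_sphere(self):
        model = fit_sphere(sphere_points(100, seed=1))
        assert np.allclose(model.center, 0.0, atol=1e-9)
        assert model.radius == pytest.approx(1.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_shifted_sphere(self):
        model = fit_sphere(sphere_points(200, radius=250.0,
                                         center=(10, 20, 30), seed=2))
        assert np.allclose(model.center, [10, 20, 30], rtol=1e-6, atol=1e-6)
        assert model.radius == pytest.approx(250.0, rel=1e-6)

    def test_noisy_hemisphere_radius_within_one_percent(self):
        errs = []
        for seed in range(20):
            pts = sphere_points(5000, radius=250.0, hemisphere=True,
                                noise_sd=2.0, seed=seed)
            errs.append(abs(fit_sphere(pts).radius - 250.0) / 250.0)
        assert np.median(errs) < 0.01

    def test_coplanar_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                               np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_sphere(np.eye(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(tx=st.floats(-500, 500), ty=st.floats(-500, 500),
           tz=st.floats(-500, 500))
    def test_translation_equivariance(self, tx, ty, tz):
        pts = sphere_points(80, radius=50.0, seed=3)
        base = fit_sphere(pts)
        moved = fit_sphere(pts + [tx, ty, tz])
        assert np.allclose(moved.center, base.center + [tx, ty, tz],
                           atol=1e-6)
        assert moved.radius == pytest.approx(base.radius, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(0.01, 100))
    def test_scale_equivariance(self, k):
        pts = sphere_points(80, radius=50.0, seed=4)
        assert fit_sphere(k * pts).radius == pytest.approx(
            k * fit_sphere(pts).radius, rel=1e-8)

    def test_r_squared_decreases_with_noise(self):
        r2 = [fit_sphere(sphere_points(2000, radius=250.0, hemisphere=True,
                                       noise_sd=sd, seed=5)).r_squared
              for sd in (0.0, 5.0, 25.0)]
        assert r2[0] == pytest.approx(1.0, abs=1e-9)
        assert r2[0] > r2[1] > r2[2]

    def test_estimator_interface(self):
        est = SphereFit().fit(sphere_points(50, radius=3.0, seed=6))
        assert est.get_params() == {}
        assert est.radius_ == pytest.approx(3.0, rel=1e-9)


class TestBeadCalibration:
    def test_identity_when_measured_equals_nominal(self):
        cal = BeadCalibration().fit([50.0, 250.0, 500.0],
                                    [50.0, 250.0, 500.0])
        assert cal.scale_ == pytest.approx(1.0)
        assert cal.r_squared_ == pytest.approx(1.0)

    def test_half_scale_measured(self):
        cal = BeadCalibration().fit([25.0, 125.0, 250.0],
                                    [50.0, 250.0, 500.0])
        assert cal.scale_ == pytest.approx(2.0)

    def test_single_radius_rejected(self):
        with pytest.raises(InsufficientDataError):
            BeadCalibration().fit([50.0, 50.0], [50.0, 50.0])


def synthetic_cap_surface(half_angle_v=30.0, half_angle_h=30.0,
                          radius=250.0, size=None):
    """Exact (noise-free) spherical-cap EyeSurface for projection tests."""
    from compeye.stack import EyeSurface

    a = radius * np.sin(np.radians(half_angle_h))
    b = radius * np.sin(np.radians(half_angle_v))
    if size is None:
        size = 2 * int(max(a, b)) + 11
    c = (size - 1) / 2.0
    yy, xx = np.indices((size, size))
    dx, dy = (xx - c), (yy - c)
    mask = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    z = np.sqrt(np.maximum(radius**2 - dx**2 - dy**2, 0.0))
    heights = np.where(mask, z - z[mask].min(), np.nan)
    return EyeSurface(heights=heights, mask=mask,
                      composite=np.zeros((size, size)), delta_h=1.0,
                      pixel_scale=1.0)


class TestProjectionAndFov:
    def test_circular_cap_boundary_at_half_angle(self):
        surf = synthetic_cap_surface(30.0, 30.0)
        model = fit_sphere(surf.points())
        proj = spherical_project(surf, model)
        radii = np.hypot(proj["boundary"][:, 0], proj["boundary"][:, 1])
        assert radii.mean() == pytest.approx(30.0, rel=0.03)

    def test_elliptical_cap_semiaxes(self):
        surf = synthetic_cap_surface(30.0, 40.0)
        model = fit_sphere(surf.points())
        fov = measure_fov(spherical_project(surf, model)["boundary"])
        assert fov.vertical == pytest.approx(60.0, rel=0.05)
        assert fov.horizontal == pytest.approx(80.0, rel=0.05)

    def test_fov_circle_exact(self):
        t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        boundary = np.column_stack([30 * np.cos(t), 30 * np.sin(t)])
        fov = measure_fov(boundary)
        assert fov.vertical == pytest.approx(60.0, abs=1e-6)
        assert fov.horizontal == pytest.approx(60.0, abs=1e-6)
        assert fov.vh_ratio == pytest.approx(1.0, abs=1e-6)
        assert fov.area == pytest.approx(np.pi * 30 * 30, rel=1e-6)

    def test_fov_ellipse_components(self):
        t = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        boundary = np.column_stack([30 * np.cos(t), 40 * np.sin(t)])
        fov = measure_fov(boundary)  # major axis along chart y = vertical
        assert fov.vertical == pytest.approx(80.0, abs=1e-6)
        assert fov.horizontal == pytest.approx(60.0, abs=1e-6)
        assert fov.vh_ratio == pytest.approx(80 / 60, rel=1e-6)

    def test_fov_underdetermined(self):
        with pytest.raises(DegenerateGeometryError):
            measure_fov(np.zeros((4, 2)))

    def test_generator_cap_fov_via_full_pipeline(self, eye_stack_default,
                                                 eye_surface_default):
        truth = eye_stack_default["truth"]
        model = fit_sphere(eye_surface_default.points())
        assert model.radius == pytest.approx(truth["radius"], rel=0.05)
        fov = measure_fov(
            spherical_project(eye_surface_default, model)["boundary"])
        assert fov.vertical == pytest.approx(truth["fov_vertical"], rel=0.05)
        assert fov.horizontal == pytest.approx(truth["fov_horizontal"],
                                               rel=0.05)
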