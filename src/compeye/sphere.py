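"""Sphere fitting, spherical projection, and field-of-view measurement.

Fly eyes are approximately spherical, so the reconstructed surface is
summarized by a least-squares sphere.  The linearized system

    f = A c,   f = [x^2+y^2+z^2],  A = [2x, 2y, 2z, 1],
    c = [x0, y0, z0, r^2 - x0^2 - y0^2 - z0^2]^T

is solved by ordinary least squares for the center, and the radius is
the mean distance of the points to that center.  The eye radius R enters
the interommatidial angle as dphi = D / R.

The masked surface is then spherically projected about the fitted
center (azimuthal-equidistant chart about the centroid ray, where chart
distance equals visual angle), and the field of view is the ellipse
fitted to the eye outline in that chart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel
from sklearn.base import BaseEstimator

from .exceptions import DegenerateGeometryError, InsufficientDataError
from .stack import EyeSurface, FocusStack, reconstruct_surface

__all__ = [
    "SphereModel",
    "FieldOfView",
    "SphereFit",
    "BeadCalibration",
    "fit_sphere",
    "validate_on_beads",
    "spherical_project",
    "measure_fov",
]


@dataclass
class SphereModel:
    """Fitted sphere: center (x0, y0, z0) and radius r in micrometers.

    ``r_squared`` is the coefficient of determination of the spherical
    model evaluated on surface heights (observed z vs sphere-predicted z).
    """

    center: np.ndarray
    radius: float
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "radius": float(self.radius),
            "r_squared": float(self.r_squared),
        }


@dataclass
class FieldOfView:
    """Elliptical field of view in degrees (area in square degrees)."""

    vertical: float
    horizontal: float
    area: float
    vh_ratio: float

    def to_dict(self) -> dict:
        return {
            "vertical": self.vertical,
            "horizontal": self.horizontal,
            "area": self.area,
            "vh_ratio": self.vh_ratio,
        }


class SphereFit(BaseEstimator):
    """Least-squares sphere fit to a 3D point cloud.

    Fitted attributes
    -----------------
    center_ : ndarray, shape (3,)
    radius_ : float
        Mean distance of the points to the fitted center.
    r_squared_ : float
        1 - SS_resid/SS_total of observed z against sphere-predicted z
        (clipped to [0, 1]).  On exact spheres this is 1.
    """

    def fit(self, points: np.ndarray) -> "SphereFit":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DegenerateGeometryError("points must be an (N, 3) array")
        if pts.shape[0] < 4:
            raise InsufficientDataError("sphere fit needs at least 4 points")

        f = (pts**2).sum(axis=1)
        A = np.column_stack([2.0 * pts, np.ones(len(pts))])
        # Coplanar input makes A rank-deficient in a way that leaves the
        # center unidentifiable along the plane normal.
        if np.linalg.matrix_rank(A) < 4:
            raise DegenerateGeometryError(
                "points are coplanar or otherwise degenerate; "
                "the sphere center is not identifiable"
            )
        c, *_ = np.linalg.lstsq(A, f, rcond=None)
        center = c[:3]
        dists = np.linalg.norm(pts - center, axis=1)
        radius = float(dists.mean())
        if radius <= 0:
            raise DegenerateGeometryError("fitted radius is non-positive")

        self.center_ = center
        self.radius_ = radius
        self.r_squared_ = self._height_r2(pts, center, radius)
        self.model_ = SphereModel(center, radius, self.r_squared_)
        return self

    @staticmethod
    def _height_r2(pts: np.ndarray, center: np.ndarray, radius: float) -> float:
        z = pts[:, 2]
        dxy2 = ((pts[:, :2] - center[:2]) ** 2).sum(axis=1)
        disc = np.sqrt(np.maximum(radius**2 - dxy2, 0.0))
        # each point is explained by the nearer sphere branch
        sign = np.where(z >= center[2], 1.0, -1.0)
        z_hat = center[2] + sign * disc
        ss_res = ((z - z_hat) ** 2).sum()
        ss_tot = ((z - z.mean()) ** 2).sum()
        if ss_tot <= 0:
            return 1.0 if ss_res <= 1e-12 * max(1.0, radius**2) else 0.0
        return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))

    def predict_height(self, xy: np.ndarray) -> np.ndarray:
        """Sphere-predicted z at in-plane coordinates (upper branch)."""
        xy = np.asarray(xy, dtype=float)
        dxy2 = ((xy - self.center_[:2]) ** 2).sum(axis=1)
        return self.center_[2] + np.sqrt(
            np.maximum(self.radius_**2 - dxy2, 0.0)
        )


def fit_sphere(points: np.ndarray) -> SphereModel:
    """OLS sphere fit; see :class:`SphereFit`."""
    return SphereFit().fit(points).model_


class BeadCalibration(BaseEstimator):
    """Through-origin regression of nominal bead radius on measured radius.

    Calibration beads of known nominal radius are run through the full
    focus-stack + sphere-fit pipeline; the fitted scalar maps measured
    radii onto true radii.

    Fitted attributes
    -----------------
    scale_ : float
        OLS slope through the origin (nominal = scale * measured).
    r_squared_ : float
        Coefficient of determination of the through-origin model
        against the centered total sum of squares.
    """

    def fit(self, measured: np.ndarray, nominal: np.ndarray) -> "BeadCalibration":
        measured = np.asarray(measured, dtype=float)
        nominal = np.asarray(nominal, dtype=float)
        if len(np.unique(nominal)) < 2:
            raise InsufficientDataError(
                "bead calibration needs at least 2 distinct nominal radii"
            )
        self.scale_ = float((nominal * measured).sum() / (measured**2).sum())
        resid = nominal - self.scale_ * measured
        ss_tot = ((nominal - nominal.mean()) ** 2).sum()
        self.r_squared_ = float(1.0 - (resid**2).sum() / ss_tot) if ss_tot > 0 else 1.0
        return self

    def predict(self, measured: np.ndarray) -> np.ndarray:
        return self.scale_ * np.asarray(measured, dtype=float)


def validate_on_beads(bead_stacks: list[FocusStack],
                      nominal_radii: list[float],
                      window: int = 5,
                      mask_threshold: float = 0.1) -> BeadCalibration:
    """Run bead stacks through the pipeline and calibrate measured radii.

    Each stack is surface-reconstructed and sphere-fitted; nominal radius
    is regressed through the origin on the measured radius.
    """
    measured = []
    for stk in bead_stacks:
        surface = reconstruct_surface(stk, window=window,
                                      mask_threshold=mask_threshold)
        measured.append(fit_sphere(surface.points()).radius)
    cal = BeadCalibration().fit(np.asarray(measured),
                                np.asarray(nominal_radii, dtype=float))
    cal.measured_radii_ = np.asarray(measured)
    return cal


def _local_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (and to each other).

    e2 is chosen so that its projection aligns with the image +y (row)
    direction, keeping 'up' in the chart tied to anatomical vertical.
    """
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e2 = ref - np.dot(ref, axis) * axis
    e2 /= np.linalg.norm(e2)
    e1 = np.cross(e2, axis)
    return e1, e2


def spherical_project(surface: EyeSurface, model: SphereModel,
                      max_boundary_points: int = 720) -> dict:
    """Project the masked surface onto an angle chart about the fitted center.

    Each masked pixel is mapped to its direction from the sphere center;
    the polar axis points from the center to the mean surface direction
    (the centroid ray).  The chart is azimuthal-equidistant: a point at
    angular distance theta from the axis and azimuth phi maps to
    ``(theta*cos(phi), theta*sin(phi))`` in degrees, so chart distances
    are visual angles.

    Returns a dict with ``points`` (all masked pixels in chart coords,
    degrees), ``intensities`` (composite values at those pixels),
    ``boundary`` (ordered mask-outline points in chart coords, subsampled
    to at most ``max_boundary_points``), and ``axis`` (the polar axis).
    """
    if not surface.mask.any():
        raise InsufficientDataError("surface mask is empty")
    pts = surface.points()
    vec = pts - model.center
    norms = np.linalg.norm(vec, axis=1)
    units = vec / norms[:, None]
    axis = units.mean(axis=0)
    axis /= np.linalg.norm(axis)
    e1, e2 = _local_frame(axis)

    def to_chart(u: np.ndarray) -> np.ndarray:
        ct = np.clip(u @ axis, -1.0, 1.0)
        theta = np.degrees(np.arccos(ct))
        phi = np.arctan2(u @ e2, u @ e1)
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])

    chart = to_chart(units)

    boundary_mask = surface.mask & ~ndimage.binary_erosion(surface.mask)
    rows, cols = np.nonzero(boundary_mask)
    bpts = np.column_stack([
        cols * surface.pixel_scale,
        rows * surface.pixel_scale,
        surface.heights[rows, cols],
    ])
    bvec = bpts - model.center
    bunits = bvec / np.linalg.norm(bvec, axis=1)[:, None]
    bchart = to_chart(bunits)
    # order by azimuth so the outline is traversable
    order = np.argsort(np.arctan2(bchart[:, 1], bchart[:, 0]))
    bchart = bchart[order]
    if len(bchart) > max_boundary_points:
        idx = np.linspace(0, len(bchart) - 1, max_boundary_points).astype(int)
        bchart = bchart[idx]

    rows_m, cols_m = np.nonzero(surface.mask)
    return {
        "points": chart,
        "intensities": surface.composite[rows_m, cols_m],
        "boundary": bchart,
        "axis": axis,
    }


def measure_fov(boundary: np.ndarray,
                vertical_axis: tuple[float, float] = (0.0, 1.0)) -> FieldOfView:
    """Fit an ellipse to the eye outline in angle coordinates.

    ``boundary`` is (N, 2) in degrees.  The ellipse axis better aligned
    with ``vertical_axis`` (the anatomical up direction recorded with
    the image, default the chart y axis) is reported as the vertical
    FOV component; the other as horizontal.  Area is the ellipse area
    in square degrees.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[0] < 5:
        raise DegenerateGeometryError(
            "ellipse fit needs at least 5 boundary points"
        )
    model = EllipseModel.from_estimate(boundary)
    if not model:
        raise DegenerateGeometryError("ellipse fit failed on boundary points")
    a, b = model.axis_lengths
    theta = model.theta
    # axis directions in the chart
    dir_a = np.array([np.cos(theta), np.sin(theta)])
    dir_b = np.array([-np.sin(theta), np.cos(theta)])
    v = np.asarray(vertical_axis, dtype=float)
    v = v / np.linalg.norm(v)
    if abs(dir_a @ v) >= abs(dir_b @ v):
        vert, horiz = a, b
    else:
        vert, horiz = b, a
    vertical = 2.0 * vert
    horizontal = 2.0 * horiz
    return FieldOfView(
        vertical=float(vertical),
        horizontal=float(horizontal),
        area=float(np.pi * vertical / 2.0 * horizontal / 2.0),
        vh_ratio=float(vertical / horizontal),
    )
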