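"""Optical limits of a spherical compound eye.

For a spherical eye of radius R tiled with facets of diameter D, the
interommatidial angle is dphi = D/R, the corneal lens area is
A = pi (D/2)^2, and the longest wavelength the eye can resolve at the
diffraction limit is lambda_max < 2 D dphi (D in nm, dphi in radians).
A Gaussian-MTF photon-noise model illustrates the spatial-summation
trade-off: pooling neighboring channels widens the effective acceptance
angle (lowering the modulation transfer function everywhere) but
collects more photons (raising signal-to-noise at low spatial
frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["EyeMetrics", "SummationModel", "derive_metrics", "mtf_snr_curves"]


@dataclass
class EyeMetrics:
    """Per-eye optical summary.

    Angles are stored in radians; ``interommatidial_angle_deg`` is the
    degree rendering for interfaces.
    """

    facet_diameter: float            # D, micrometers
    eye_radius: float                # R, micrometers
    interommatidial_angle: float     # dphi = D/R, radians
    interommatidial_angle_deg: float
    lens_area: float                 # A = pi (D/2)^2, square micrometers
    lambda_max: float                # 2 D dphi, nanometers
    ommatidial_density: float | None = None  # count per mm^2 of eye surface
    eye_area: float | None = None    # mm^2
    count: int | None = None
    fov: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "facet_diameter_um": self.facet_diameter,
            "eye_radius_um": self.eye_radius,
            "interommatidial_angle_rad": self.interommatidial_angle,
            "interommatidial_angle_deg": self.interommatidial_angle_deg,
            "lens_area_um2": self.lens_area,
            "lambda_max_nm": self.lambda_max,
        }
        if self.ommatidial_density is not None:
            out["ommatidial_density_per_mm2"] = self.ommatidial_density
        if self.count is not None:
            out["count"] = self.count
        if self.eye_area is not None:
            out["eye_area_mm2"] = self.eye_area
        if self.fov is not None:
            out["fov"] = self.fov
        return out


def derive_metrics(facet_diameter: float, eye_radius: float,
                   count: int | None = None,
                   eye_area: float | None = None,
                   fov: dict | None = None) -> EyeMetrics:
    """Closed-form optical parameters from D (um) and R (um).

    ``count`` and ``eye_area`` (mm^2) additionally give the ommatidial
    density, count / eye_area.
    """
    if not (facet_diameter > 0 and eye_radius > 0):
        raise ValidationError("facet diameter and eye radius must be positive")
    dphi = facet_diameter / eye_radius
    density = None
    if count is not None and eye_area is not None:
        if not eye_area > 0:
            raise ValidationError("eye_area must be positive")
        density = count / eye_area
    return EyeMetrics(
        facet_diameter=facet_diameter,
        eye_radius=eye_radius,
        interommatidial_angle=dphi,
        interommatidial_angle_deg=float(np.degrees(dphi)),
        lens_area=float(np.pi * (facet_diameter / 2.0) ** 2),
        lambda_max=2.0 * (facet_diameter * 1000.0) * dphi,
        ommatidial_density=density,
        eye_area=eye_area,
        count=count,
        fov=fov,
    )


@dataclass
class SummationModel:
    """Parameters of the MTF / SNR spatial-summation model.

    acceptance_angle : half-width of the photoreceptor acceptance
        function, degrees.
    pooling_angle : extra angular width contributed by neural pooling,
        degrees (0 = no summation).
    photon_rate : effective photons per channel per integration time.
    contrast : stimulus Michelson contrast.
    frequencies : spatial-frequency grid, cycles/degree.
    """

    acceptance_angle: float = 1.5
    pooling_angle: float = 1.5
    photon_rate: float = 100.0
    contrast: float = 1.0
    frequencies: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 201))

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size == 0:
            raise ValidationError("frequency grid is empty")
        if not self.acceptance_angle > 0:
            raise ValidationError("acceptance_angle must be positive")
        if self.pooling_angle < 0:
            raise ValidationError("pooling_angle must be >= 0")
        if not self.photon_rate > 0:
            raise ValidationError("photon_rate must be positive")


def _gaussian_mtf(nu: np.ndarray, delta_rho: float) -> np.ndarray:
    # Gaussian acceptance function of half-width delta_rho (degrees)
    return np.exp(-((np.pi * delta_rho * nu) ** 2) / (4.0 * np.log(2.0)))


def mtf_snr_curves(model: SummationModel) -> dict:
    """MTF and SNR per spatial frequency, with and without pooling.

    Pooling widens the effective acceptance angle to
    sqrt(acceptance^2 + pooling^2), lowering the MTF everywhere, but
    multiplies the photon catch by the pooled/unpooled area ratio, so
    SNR(nu) = contrast * MTF(nu) * sqrt(photon_rate * area_gain) gains
    at low frequencies and loses above a crossover.
    """
    nu = model.frequencies
    rho = model.acceptance_angle
    rho_eff = float(np.hypot(rho, model.pooling_angle))
    area_gain = (rho_eff / rho) ** 2

    mtf_unpooled = _gaussian_mtf(nu, rho)
    mtf_pooled = _gaussian_mtf(nu, rho_eff)
    snr_unpooled = model.contrast * mtf_unpooled * np.sqrt(model.photon_rate)
    snr_pooled = (model.contrast * mtf_pooled
                  * np.sqrt(model.photon_rate * area_gain))
    return {
        "frequencies": nu,
        "mtf_unpooled": mtf_unpooled,
        "mtf_pooled": mtf_pooled,
        "snr_unpooled": snr_unpooled,
        "snr_pooled": snr_pooled,
        "effective_acceptance_angle": rho_eff,
        "area_gain": area_gain,
    }
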